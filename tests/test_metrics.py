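"""Contrast metrics, transducers and the wide-field gain-control response."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from battenberg import (
    BattenbergSpec,
    ContrastMap,
    ModelParams,
    contrast_average,
    contrast_sum,
    energy,
    gain_control_response,
    lf_summed_response,
    make_battenberg,
    map_response,
    max_contrast,
    michelson,
    rms_contrast,
    toy_response,
    weber_contrast_map,
)


def lf_transducer(c, p=2.4, q=2.0, z=1.0):
    return c**p / (z + c**q)


class TestWeberMap:
    def test_uniform_image_is_all_zero(self):
        m = weber_contrast_map(np.ones((8, 8)))
        assert np.all(m.values == 0)

    def test_two_level_image(self):
        m = weber_contrast_map(np.array([[0.5, 1.5]]))
        assert np.allclose(m.values, [[50.0, 50.0]])

    def test_battenberg_peak_equals_component_contrast(self):
        img = make_battenberg(BattenbergSpec(8, 8))
        assert max_contrast(weber_contrast_map(img)) == pytest.approx(8.0, abs=1e-9)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            weber_contrast_map(np.zeros((4, 4)))


class TestSimpleMetrics:
    def test_square_wave_has_full_michelson_and_rms(self):
        img = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert michelson(img) == pytest.approx(100.0)
        assert rms_contrast(img) == pytest.approx(100.0)

    def test_uniform_image_scores_zero_everywhere(self):
        img = np.ones((10, 10))
        m = weber_contrast_map(img)
        assert michelson(img) == 0
        assert rms_contrast(img) == 0
        for f in (energy, contrast_sum, contrast_average, max_contrast):
            assert f(m) == 0

    def test_sinusoid_rms_is_contrast_over_sqrt2(self):
        c = 32.0
        y = np.arange(400)
        img = np.tile(1.0 + c / 100 * np.sin(2 * np.pi * y / 20), (50, 1))
        assert rms_contrast(img) == pytest.approx(c / np.sqrt(2), rel=1e-9)

    def test_map_reductions_on_known_values(self):
        m = ContrastMap(np.array([[3.0, 4.0]]))
        assert energy(m) == 25.0
        assert contrast_sum(m) == 7.0
        assert contrast_average(m) == 3.5
        assert max_contrast(m) == 4.0


class TestToyModels:
    def test_gain_control_at_zero_is_zero(self):
        assert toy_response("ms", 0, 0) == 0.0

    def test_gain_control_frozen_value(self):
        # 2*8^2.4 / (1 + 2*8^2), evaluated independently at high precision
        assert toy_response("ms", 8, 8) == pytest.approx(2.27958743317241, rel=1e-12)

    def test_summed_transducer_frozen_value(self):
        assert toy_response("lf", 4, 8) == pytest.approx(3.9007355584882224, rel=1e-12)
        assert toy_response("lf", 4, 8) == pytest.approx(
            lf_transducer(4) + lf_transducer(8), rel=1e-12
        )

    def test_simple_toys(self):
        assert toy_response("max", 4, 8) == 8.0
        assert toy_response("linsum", 4, 8) == 12.0
        assert toy_response("energy", 4, 8) == 80.0

    def test_adding_a_weak_component_lowers_the_gain_control_response(self):
        """The paradox at response level: suppression outweighs excitation."""
        assert toy_response("ms", 4, 8) < toy_response("ms", 0, 8)
        # ... but not for any of the other models
        for model in ("max", "linsum", "energy", "lf"):
            assert toy_response(model, 4, 8) >= toy_response(model, 0, 8)

    def test_unknown_model_and_negative_contrast_rejected(self):
        with pytest.raises(ValueError, match="model_id"):
            toy_response("rms", 4, 8)
        with pytest.raises(ValueError):
            toy_response("ms", -1, 8)

    @given(st.floats(0.5, 99.0), st.floats(1.01, 2.0))
    def test_gain_control_increases_with_the_common_level(self, c, factor):
        assert toy_response("ms", c * factor, c * factor) > toy_response("ms", c, c)


class TestMapModels:
    def test_single_location_map_equals_one_component_toy(self):
        m = ContrastMap(np.array([[8.0]]))
        assert gain_control_response(m) == pytest.approx(
            toy_response("ms", 8, 0), rel=1e-12
        )
        assert lf_summed_response(m) == pytest.approx(lf_transducer(8), rel=1e-12)

    def test_all_zero_map_responds_zero(self):
        m = ContrastMap(np.zeros((5, 5)))
        assert gain_control_response(m) == 0.0
        assert lf_summed_response(m) == 0.0

    def test_element_map_equals_toy_under_z_rescaling(self):
        """With z scaled by the per-component element count, the element-level
        gain-control response is exactly the toy response."""
        from battenberg.matching import MatchingCondition, stimulus_response

        cond = MatchingCondition(test_A=4.0, test_B=8.0, granularity="element",
                                 params=ModelParams(z=200.0))
        r_elem = stimulus_response(cond)  # 400-entry map, z = 200 elements/component
        assert r_elem == pytest.approx(
            toy_response("ms", 4, 8, ModelParams(z=1.0)), rel=1e-12
        )

    def test_element_map_close_to_toy_at_suprathreshold_contrast(self):
        from battenberg.matching import MatchingCondition, stimulus_response

        cond = MatchingCondition(test_A=4.0, test_B=8.0, granularity="element")
        assert stimulus_response(cond) == pytest.approx(
            toy_response("ms", 4, 8), rel=2e-2
        )

    def test_minkowski_k1_equals_linear_summation(self):
        m = ContrastMap(np.array([4.0, 8.0, 2.0]))
        assert lf_summed_response(m, ModelParams(minkowski_k=1)) == pytest.approx(
            lf_summed_response(m), rel=1e-12
        )

    def test_minkowski_map_frozen_value(self):
        m = ContrastMap(np.array([4.0, 8.0]))
        expected = (lf_transducer(4) ** 4 + lf_transducer(8) ** 4) ** 0.25
        assert lf_summed_response(m, ModelParams(minkowski_k=4)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_minkowski_limit_approaches_max_transducer(self):
        m = ContrastMap(np.array([4.0, 8.0, 1.0]))
        r = lf_summed_response(m, ModelParams(minkowski_k=256))
        assert r == pytest.approx(lf_transducer(8.0), rel=1e-2)

    def test_area_growth_leaves_gain_control_asymptotically_flat(self):
        """Doubling the stimulus area inflates sum/energy metrics but the
        gain-control response converges to c^(p-q)."""
        c = 8.0
        small = ContrastMap(np.full(400, c))
        big = ContrastMap(np.full(160000, c))
        asymptote = c**0.4
        assert abs(gain_control_response(big) - asymptote) < abs(
            gain_control_response(small) - asymptote
        )
        assert gain_control_response(big) == pytest.approx(asymptote, rel=1e-3)
        assert contrast_sum(big) == 400 * contrast_sum(small)

    def test_map_dispatch_matches_direct_calls(self):
        m = ContrastMap(np.array([4.0, 8.0]))
        assert map_response("max", m) == 8.0
        assert map_response("linsum", m) == 12.0
        assert map_response("energy", m) == 80.0
        assert map_response("ms", m) == gain_control_response(m)
        assert map_response("lf", m) == lf_summed_response(m)
        with pytest.raises(ValueError):
            map_response("nope", m)


class TestModelParams:
    @pytest.mark.parametrize(
        "kw",
        [dict(p=2.0, q=2.0), dict(p=1.8, q=2.0), dict(z=-1.0), dict(minkowski_k=0.5)],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_negative_map_values_rejected(self):
        with pytest.raises(ValueError):
            ContrastMap(np.array([-1.0, 2.0]))
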