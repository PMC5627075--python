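"""Point-of-subjective-equality (PSE) prediction.

For a test stimulus with component contrasts (A, B) and a matching-stimulus
family ('single': one component at level m, the other at 0; 'dual': both at
m), the predicted PSE is the level m at which the model's response to the
match equals its response to the test.  Model responses can be computed at
three granularities:

* ``toy``       — closed forms on the two component contrasts only;
* ``element``   — one map entry per grid element;
* ``pixelwise`` — the model applied to the rendered image, pixel by pixel,
  optionally after a log-Gabor filtering front end.

Every implemented model's response is strictly increasing in the common
level of the match family (guaranteed for p > q and verified numerically
before each solve), so the PSE is found by bisection in log contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .filtering import FilterParams, filter_contrast_map
from .metrics import MODEL_IDS, ContrastMap, ModelParams
from .stimulus import BattenbergSpec, checker_mask, make_battenberg, matching_spec

__all__ = [
    "MatchingCondition",
    "PSEResult",
    "MatchEngine",
    "stimulus_response",
    "predict_pse",
    "matching_curve",
    "DEFAULT_A_GRID",
]

#: Default grid of test 'A' contrasts (%), octave-spaced from 0 to 32 with
#: the fixed 8% 'B' pedestal in the middle.
DEFAULT_A_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)

GRANULARITIES = ("toy", "element", "pixelwise")
MATCH_MODES = ("single", "dual")

_M_MAX = 200.0  # solver bracket top, %; beyond physical 100% on purpose
_M_MIN = 1e-6
_MAX_ITER = 60
_REL_TOL = 1e-9


@dataclass(frozen=True)
class MatchingCondition:
    """One cell of the matching experiment plus the model pipeline to run.

    ``test_B`` defaults to the 8% pedestal used throughout the experiments.
    ``granularity`` selects toy/element/pixelwise evaluation; spatial
    filtering (``filtered=True``) only makes sense on rendered images and is
    rejected for toy granularity.
    """

    test_A: float
    test_B: float = 8.0
    cluster_size_j: int = 1
    match_mode: str = "single"
    model_id: str = "ms"
    granularity: str = "toy"
    filtered: bool = False
    params: ModelParams = field(default_factory=ModelParams)
    filter_params: FilterParams = field(default_factory=FilterParams)
    n_elements: int = 20
    element_px: int = 20
    px_per_deg: float = 48.0
    parity: int = 0
    mean_luminance: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if self.match_mode not in MATCH_MODES:
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.granularity == "toy" and self.filtered:
            raise ValueError("toy granularity has no image to filter")
        if self.test_A < 0 or self.test_B < 0:
            raise ValueError("test contrasts must be >= 0")

    @property
    def geometry(self) -> dict:
        return dict(
            cluster_size_j=self.cluster_size_j,
            n_elements=self.n_elements,
            element_px=self.element_px,
            px_per_deg=self.px_per_deg,
            parity=self.parity,
            mean_luminance=self.mean_luminance,
        )


@dataclass(frozen=True)
class PSEResult:
    """Predicted PSE plus solver diagnostics.

    ``above_physical`` flags a mathematically valid solution beyond 100%
    contrast (some failing models need one).  A non-converged result carries
    ``pse = nan`` and the bracket that failed.
    """

    pse: float
    iterations: int
    bracket: tuple[float, float]
    converged: bool
    residual: float
    above_physical: bool = False


def _element_map(spec: BattenbergSpec) -> ContrastMap:
    labels = checker_mask(
        spec.n_elements, spec.cluster_size_j, spec.parity, truncate=True
    )
    values = np.where(labels == 0, spec.contrast_A, spec.contrast_B).astype(float)
    return ContrastMap(values, "element_toy")


def _image_map(spec: BattenbergSpec, cond: MatchingCondition) -> ContrastMap:
    img = make_battenberg(spec)
    if cond.filtered:
        return filter_contrast_map(img, cond.filter_params)
    return metrics.weber_contrast_map(img)


def stimulus_response(cond: MatchingCondition, stimulus=None) -> float:
    """Model response to a stimulus under the condition's pipeline.

    ``stimulus`` may be None (the condition's own test stimulus), an (A, B)
    contrast pair, or a :class:`~battenberg.stimulus.LuminanceImage` (pixelwise
    granularity only).
    """
    if stimulus is None:
        stimulus = (cond.test_A, cond.test_B)
    if isinstance(stimulus, tuple):
        A, B = stimulus
        if cond.granularity == "toy":
            return metrics.toy_response(cond.model_id, A, B, cond.params)
        spec = BattenbergSpec(contrast_A=A, contrast_B=B, **cond.geometry)
        m = _element_map(spec) if cond.granularity == "element" else _image_map(spec, cond)
        return metrics.map_response(cond.model_id, m, cond.params)
    if cond.granularity == "toy":
        raise ValueError("toy granularity takes (A, B) contrasts, not an image")
    m = (
        filter_contrast_map(stimulus, cond.filter_params)
        if cond.filtered
        else metrics.weber_contrast_map(stimulus)
    )
    return metrics.map_response(cond.model_id, m, cond.params)


class MatchEngine:
    """Response of the matching-stimulus family as a function of its level.

    All implemented models act on contrast maps that scale linearly with the
    match level m (Weber maps and linear-filter outputs are both homogeneous
    of degree 1 in contrast), so a unit-level map is computed once and the
    per-level response reduces to cheap closed forms (power sums for the
    separable models; a vectorized map pass for the summed transducer).
    """

    def __init__(self, cond: MatchingCondition):
        self.cond = cond
        p, q, z = cond.params.p, cond.params.q, cond.params.z
        if cond.granularity == "toy":
            u = np.array([1.0, 1.0]) if cond.match_mode == "dual" else np.array([1.0, 0.0])
        elif cond.granularity == "element":
            spec = matching_spec(cond.match_mode, 1.0, **cond.geometry)
            u = _element_map(spec).values
        else:
            spec = matching_spec(cond.match_mode, 1.0, **cond.geometry)
            u = _image_map(spec, cond).values
        self._unit = u
        model = cond.model_id
        if model == "max":
            u_max = float(u.max())
            self._resp = lambda m: m * u_max
        elif model == "linsum":
            u_sum = float(u.sum())
            self._resp = lambda m: m * u_sum
        elif model == "energy":
            u_sq = float((u**2).sum())
            self._resp = lambda m: m**2 * u_sq
        elif model == "ms":
            s_p = float((u**p).sum())
            s_q = float((u**q).sum())
            self._resp = lambda m: (m**p * s_p) / (z + m**q * s_q)
        else:  # lf: not separable in m
            pos = u[u > 0]
            self._resp = lambda m: metrics.lf_summed_response(m * pos, cond.params)
        self._check_monotone()

    def match_response(self, m: float) -> float:
        """Model response to the matching stimulus at level m (%)."""
        if m < 0:
            raise ValueError(f"matching level must be >= 0 %, got {m}")
        if m == 0:
            return 0.0
        return float(self._resp(m))

    def _check_monotone(self, n: int = 33) -> None:
        grid = np.logspace(np.log10(_M_MIN), np.log10(_M_MAX), n)
        resp = np.array([self.match_response(m) for m in grid])
        if np.any(np.diff(resp) <= 0):
            raise RuntimeError(
                "match-family response is not strictly increasing in level; "
                "PSE bisection would be unsound for this model/parameter set"
            )

    def solve(self, test_response: float) -> PSEResult:
        """Find m with match_response(m) = test_response by log bisection."""
        if test_response < 0:
            raise ValueError("test response must be >= 0")
        if test_response == 0:
            return PSEResult(0.0, 0, (0.0, 0.0), True, 0.0)
        if self.match_response(_M_MAX) < test_response:
            return PSEResult(
                float("nan"), 0, (_M_MIN, _M_MAX), False,
                self.match_response(_M_MAX) - test_response,
            )
        lo, hi = np.log10(_M_MIN), np.log10(_M_MAX)
        mid, resid = lo, self.match_response(10**lo) - test_response
        it = 0
        for it in range(1, _MAX_ITER + 1):
            mid = 0.5 * (lo + hi)
            resid = self.match_response(10**mid) - test_response
            if abs(resid) <= _REL_TOL * test_response:
                break
            if resid < 0:
                lo = mid
            else:
                hi = mid
        pse = float(10**mid)
        converged = abs(resid) <= _REL_TOL * test_response
        return PSEResult(
            pse=pse,
            iterations=it,
            bracket=(float(10**lo), float(10**hi)),
            converged=converged,
            residual=float(resid),
            above_physical=pse > 100.0,
        )


def predict_pse(cond: MatchingCondition) -> PSEResult:
    """Predict the matching level at which match and test responses equate."""
    return MatchEngine(cond).solve(stimulus_response(cond))


def matching_curve(
    cond: MatchingCondition,
    a_levels=DEFAULT_A_GRID,
) -> pd.DataFrame:
    """PSEs over a grid of test 'A' contrasts at fixed B, mode, j and model.

    Returns a tidy table with columns A, mode, j, model, granularity,
    filtered, pse, converged.  The match-side response family is shared
    across the grid (it does not depend on the test contrasts).
    """
    engine = MatchEngine(cond)
    rows = []
    for a in a_levels:
        c = replace(cond, test_A=float(a))
        res = engine.solve(stimulus_response(c))
        rows.append(
            dict(
                A=float(a),
                mode=cond.match_mode,
                j=cond.cluster_size_j,
                model=cond.model_id,
                granularity=cond.granularity,
                filtered=cond.filtered,
                pse=res.pse,
                converged=res.converged,
            )
        )
    return pd.DataFrame(rows)
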