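"""Global image-contrast metrics and gain-control models.

Implements the competing candidates for a global contrast statistic:

* simple image statistics — Michelson, RMS (std/mean), MAX, contrast sum,
  contrast average and contrast energy over a map of local Weber contrasts;
* a summed Legge-Foley transducer, ``sum_i c_i^p / (z + c_i^q)``, optionally
  with Minkowski (exponent k) instead of linear summation over locations;
* the wide-field contrast gain-control response,
  ``sum_i(c_i^p) / (z + sum_i(c_i^q))``, in which excitation and suppression
  are each pooled over the whole image *before* the division.  With p > q
  this response grows without saturating in the overall contrast level, yet
  adding a weak component to a strong one can lower it — added suppression
  can outweigh added excitation, which is the paradoxical matching effect
  the simpler metrics cannot produce.

Contrast is in percent throughout: the canonical exponents (p=2.4, q=2.0,
z=1) were estimated with C expressed in %, and the numbers are not
scale-invariant.  Each model exists in "toy" form, taking just the two
component contrasts (A, B), and in map form, operating on a ContrastMap of
local contrasts at element or pixel granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stimulus import LuminanceImage

__all__ = [
    "MODEL_IDS",
    "ModelParams",
    "ContrastMap",
    "weber_contrast_map",
    "michelson",
    "rms_contrast",
    "energy",
    "contrast_sum",
    "contrast_average",
    "max_contrast",
    "toy_response",
    "gain_control_response",
    "lf_summed_response",
    "map_response",
]

#: Model identifiers accepted by :func:`toy_response` and :func:`map_response`.
MODEL_IDS = ("max", "linsum", "energy", "lf", "ms")

MAP_PROVENANCES = ("weber_pixelwise", "filter_response", "element_toy")


@dataclass(frozen=True)
class ModelParams:
    """Free symbols of the transducer/gain-control equations.

    p : excitatory (numerator) exponent; 2.4 is the canonical
        contrast-discrimination value.
    q : suppressive (denominator) exponent; must satisfy q < p or the
        response saturates instead of growing with contrast.
    z : saturation constant (contrast-units^q).  It sets the threshold knee
        of the sigmoidal transducer; well above threshold it is negligible
        and is conventionally set to 1.
    minkowski_k : optional Minkowski exponent for the summed-transducer
        model; None means linear summation (k = 1), k -> inf approaches MAX.
    """

    p: float = 2.4
    q: float = 2.0
    z: float = 1.0
    minkowski_k: float | None = None

    def __post_init__(self) -> None:
        if not self.p > self.q:
            raise ValueError(
                f"need p > q for a non-saturating response, got p={self.p}, q={self.q}"
            )
        if self.z < 0:
            raise ValueError(f"z must be >= 0, got {self.z}")
        if self.minkowski_k is not None and self.minkowski_k < 1:
            raise ValueError(f"minkowski_k must be >= 1, got {self.minkowski_k}")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ContrastMap:
    """Array of non-negative local contrast magnitudes, in percent.

    ``provenance`` records how the map was built: per-pixel Weber fractions,
    rectified spatial-filter responses, or one entry per element ("toy"
    granularity on the element grid).  Signed responses are rectified before
    they enter any exponentiated sum.
    """

    values: np.ndarray
    provenance: str = "weber_pixelwise"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("contrast map must be non-empty")
        if np.any(v < 0):
            raise ValueError("contrast map values must be >= 0 (magnitudes)")
        if self.provenance not in MAP_PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "values", v)


def _pixels(img) -> np.ndarray:
    px = img.pixels if isinstance(img, LuminanceImage) else np.asarray(img, float)
    if px.size == 0:
        raise ValueError("empty image")
    return px


def _map_values(m) -> np.ndarray:
    v = m.values if isinstance(m, ContrastMap) else np.asarray(m, float)
    if v.size == 0:
        raise ValueError("empty contrast map")
    return v


def weber_contrast_map(img: LuminanceImage | np.ndarray) -> ContrastMap:
    """Per-pixel rectified Weber contrast, 100*|L_i - L_mean|/L_mean.

    L_mean is the mean over the whole image.
    """
    px = _pixels(img)
    mean = px.mean()
    if mean <= 0:
        raise ValueError(f"mean luminance must be positive, got {mean}")
    return ContrastMap(100.0 * np.abs(px - mean) / mean, "weber_pixelwise")


def michelson(img: LuminanceImage | np.ndarray) -> float:
    """Michelson contrast 100*(Lmax - Lmin)/(Lmax + Lmin), in percent."""
    px = _pixels(img)
    lo, hi = px.min(), px.max()
    if hi + lo == 0:
        raise ValueError("Lmax + Lmin is zero")
    return float(100.0 * (hi - lo) / (hi + lo))


def rms_contrast(img: LuminanceImage | np.ndarray) -> float:
    """RMS contrast 100*std(L)/mean(L): the normalized luminance s.d., %."""
    px = _pixels(img)
    mean = px.mean()
    if mean <= 0:
        raise ValueError(f"mean luminance must be positive, got {mean}")
    return float(100.0 * px.std() / mean)


def energy(m: ContrastMap | np.ndarray) -> float:
    """Contrast energy: sum of squared local contrasts (a.u.)."""
    return float(np.sum(_map_values(m) ** 2))


def contrast_sum(m: ContrastMap | np.ndarray) -> float:
    """Sum of local contrasts (a.u.)."""
    return float(np.sum(_map_values(m)))


def contrast_average(m: ContrastMap | np.ndarray) -> float:
    """Mean local contrast (%), i.e. contrast sum normalized by area."""
    return float(np.mean(_map_values(m)))


def max_contrast(m: ContrastMap | np.ndarray) -> float:
    """Largest local contrast in the map (%)."""
    return float(np.max(_map_values(m)))


# ---------------------------------------------------------------------------
# Toy (two-parameter) models


def _lf_transducer(c, params: ModelParams):
    c = np.asarray(c, dtype=float)
    return c**params.p / (params.z + c**params.q)


def toy_response(
    model_id: str, A: float, B: float, params: ModelParams | None = None
) -> float:
    """Global-contrast response of a toy model to component contrasts (A, B) %.

    max    : MAX(A, B)
    linsum : A + B
    energy : A^2 + B^2
    lf     : A^p/(z + A^q) + B^p/(z + B^q)   (summed transducers)
    ms     : (A^p + B^p)/(z + A^q + B^q)     (wide-field gain control)
    """
    if A < 0 or B < 0:
        raise ValueError(f"contrasts must be >= 0, got A={A}, B={B}")
    params = params or ModelParams()
    p, q, z = params.p, params.q, params.z
    if model_id == "max":
        return float(max(A, B))
    if model_id == "linsum":
        return float(A + B)
    if model_id == "energy":
        return float(A**2 + B**2)
    if model_id == "lf":
        return float(_lf_transducer(A, params) + _lf_transducer(B, params))
    if model_id == "ms":
        return float((A**p + B**p) / (z + A**q + B**q))
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


# ---------------------------------------------------------------------------
# Map-level models


def gain_control_response(
    m: ContrastMap | np.ndarray, params: ModelParams | None = None
) -> float:
    """Wide-field gain-control response sum(c^p) / (z + sum(c^q)).

    Excitation and suppression are pooled over every map location before
    the division.  For a map with a single location this reduces to the
    one-component transducer c^p/(z + c^q).
    """
    params = params or ModelParams()
    c = _map_values(m)
    return float(np.sum(c**params.p) / (params.z + np.sum(c**params.q)))


def lf_summed_response(
    m: ContrastMap | np.ndarray, params: ModelParams | None = None
) -> float:
    """Summed local transducers sum_i [c_i^p / (z + c_i^q)].

    With ``params.minkowski_k`` set, linear summation over locations is
    replaced by Minkowski summation (sum t^k)^(1/k); k -> inf approaches the
    MAX over local transducer outputs.
    """
    params = params or ModelParams()
    t = _lf_transducer(_map_values(m), params)
    k = params.minkowski_k
    if k is None or k == 1:
        return float(np.sum(t))
    return float(np.sum(t**k) ** (1.0 / k))


def map_response(
    model_id: str, m: ContrastMap | np.ndarray, params: ModelParams | None = None
) -> float:
    """Apply a model over a contrast map (element- or pixel-granularity).

    The simple metrics sum/max over the map; 'ms' pools numerator and
    denominator separately (:func:`gain_control_response`); 'lf' sums local
    transducers (:func:`lf_summed_response`).
    """
    if model_id == "max":
        return max_contrast(m)
    if model_id == "linsum":
        return contrast_sum(m)
    if model_id == "energy":
        return energy(m)
    if model_id == "lf":
        return lf_summed_response(m, params)
    if model_id == "ms":
        return gain_control_response(m, params)
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
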