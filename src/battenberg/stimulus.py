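"""Battenberg stimulus synthesis.

A Battenberg stimulus is a square grid of grating micro-patterns: a
horizontal sine-wave carrier multiplied by a full-wave-rectified vertical
sine wave of half the carrier frequency.  The rectified envelope cuts the
grating into self-contained single-cycle elements whose Michelson contrast
is set element-by-element.  Alternate elements (or alternate j x j clusters
of elements) form two interdigitated components, 'A' and 'B', whose
contrasts are controlled independently.

At the default geometry (20 x 20 elements of 20 x 20 px at 48 px/deg) the
carrier frequency is 2.4 c/deg and the whole stimulus subtends ~8.3 deg.
All images are linear, normalized luminance (mean = 1.0, nominally
60 cd m^-2); display gamma is outside the model's scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "BattenbergSpec",
    "LuminanceImage",
    "checker_mask",
    "make_battenberg",
    "make_matching_stimulus",
    "save_image",
    "load_image",
]


@dataclass(frozen=True)
class BattenbergSpec:
    """Full parametric description of a Battenberg test or matching stimulus.

    Parameters
    ----------
    contrast_A, contrast_B : float
        Michelson contrast of the 'A' and 'B' checker components, in percent
        (0-100).
    cluster_size_j : int
        Side length, in elements, of the uniform clusters that alternate in
        the checker arrangement.  j = 1 interdigitates single elements.
    n_elements : int
        Grid side length in elements.
    element_px : int
        Pixels per element side; one full carrier cycle per element.
    px_per_deg : float
        Spatial sampling density.
    parity : int
        0 or 1; selects which checker phase carries the 'A' component.  The
        two arrangements were shown with equal probability in the
        experiments this stimulus family comes from.
    mean_luminance : float
        Normalized mean luminance (1.0 represents the nominal 60 cd m^-2).
    duration_ms, isi_ms : float
        Presentation metadata only; no computation depends on time.
    """

    contrast_A: float
    contrast_B: float
    cluster_size_j: int = 1
    n_elements: int = 20
    element_px: int = 20
    px_per_deg: float = 48.0
    parity: int = 0
    mean_luminance: float = 1.0
    duration_ms: float = field(default=100.0, compare=False)
    isi_ms: float = field(default=400.0, compare=False)

    def __post_init__(self) -> None:
        for name in ("contrast_A", "contrast_B"):
            c = getattr(self, name)
            if not 0.0 <= c <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100] %, got {c}")
        if self.cluster_size_j < 1:
            raise ValueError(f"cluster_size_j must be >= 1, got {self.cluster_size_j}")
        if self.cluster_size_j > self.n_elements:
            raise ValueError(
                f"cluster_size_j={self.cluster_size_j} exceeds grid of "
                f"{self.n_elements} elements"
            )
        if self.n_elements < 1 or self.element_px < 2:
            raise ValueError("grid must have >= 1 element of >= 2 px")
        if self.mean_luminance <= 0:
            raise ValueError("mean_luminance must be positive")
        if self.parity not in (0, 1):
            raise ValueError(f"parity must be 0 or 1, got {self.parity}")

    @property
    def carrier_freq_cpd(self) -> float:
        """Carrier spatial frequency in cycles/deg (one cycle per element)."""
        return self.px_per_deg / self.element_px

    @property
    def size_px(self) -> int:
        return self.n_elements * self.element_px

    def with_contrasts(self, contrast_A: float, contrast_B: float) -> "BattenbergSpec":
        d = asdict(self)
        d.update(contrast_A=contrast_A, contrast_B=contrast_B)
        return BattenbergSpec(**d)


@dataclass(frozen=True)
class LuminanceImage:
    """2-D array of linear normalized luminance with its sampling density."""

    pixels: np.ndarray
    px_per_deg: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        object.__setattr__(self, "pixels", px)

    @property
    def mean_luminance(self) -> float:
        return float(self.pixels.mean())


def checker_mask(
    n_elements: int,
    cluster_size_j: int,
    parity: int = 0,
    *,
    truncate: bool = False,
) -> np.ndarray:
    """Element-level checkerboard of 'A'/'B' labels.

    Returns an (n, n) integer array where 0 marks 'A' elements and 1 marks
    'B' elements, arranged as an alternating checkerboard of j x j uniform
    clusters.  Flipping ``parity`` swaps every label.

    When ``cluster_size_j`` does not divide ``n_elements`` the default is an
    error.  With ``truncate=True`` the mask is built on the smallest
    j-divisible virtual grid and centre-cropped to n x n, so clusters at the
    border are truncated half-clusters; this is how a j=8 pattern tiles a
    20-element grid.
    """
    n, j = int(n_elements), int(cluster_size_j)
    if n < 1 or j < 1:
        raise ValueError("n_elements and cluster_size_j must be positive")
    if parity not in (0, 1):
        raise ValueError(f"parity must be 0 or 1, got {parity}")
    if n % j != 0 and not truncate:
        raise ValueError(
            f"cluster_size_j={j} does not divide n_elements={n}; "
            "pass truncate=True for a centre-cropped tiling"
        )
    n_virtual = math.ceil(n / j) * j
    offset = (n_virtual - n) // 2
    idx = (np.arange(n) + offset) // j
    labels = (idx[:, None] + idx[None, :] + parity) % 2
    return labels.astype(np.int8)


def _element_profile(element_px: int) -> np.ndarray:
    """Unit-contrast modulation of one element: carrier x rectified envelope.

    The carrier is a horizontal grating (one full sine cycle down the
    element, zero crossings at the element boundaries); the envelope is one
    half-cycle of a rectified vertical sine (zero at the left/right element
    edges, 1 at the centre column).  Both factors reach 1 simultaneously, so
    an element of contrast c attains peak Weber contrast exactly c.
    """
    e = element_px
    carrier = np.sin(2.0 * np.pi * np.arange(e) / e)  # varies down rows
    envelope = np.abs(np.sin(np.pi * np.arange(e) / e))  # varies across columns
    return np.outer(carrier, envelope)


def make_battenberg(spec: BattenbergSpec) -> LuminanceImage:
    """Render a Battenberg stimulus as a linear luminance image.

    Each element carries exactly one carrier cycle windowed by the rectified
    envelope; element boundaries sit at mean luminance.  'A'-labelled
    elements carry ``contrast_A``, 'B'-labelled elements ``contrast_B``.
    """
    labels = checker_mask(
        spec.n_elements, spec.cluster_size_j, spec.parity, truncate=True
    )
    contrast = np.where(labels == 0, spec.contrast_A, spec.contrast_B) / 100.0
    tile = _element_profile(spec.element_px)
    modulation = np.kron(contrast, tile)
    pixels = spec.mean_luminance * (1.0 + modulation)
    return LuminanceImage(pixels=pixels, px_per_deg=spec.px_per_deg)


def make_matching_stimulus(
    mode: str,
    level_m: float,
    *,
    cluster_size_j: int = 1,
    n_elements: int = 20,
    element_px: int = 20,
    px_per_deg: float = 48.0,
    parity: int = 0,
    mean_luminance: float = 1.0,
) -> LuminanceImage:
    """Render a 'single' or 'dual' component matching stimulus.

    single : one checker component at ``level_m`` %, the other at 0 %.
    dual   : both components at ``level_m`` %.
    """
    if level_m < 0:
        raise ValueError(f"matching level must be >= 0 %, got {level_m}")
    spec = matching_spec(
        mode,
        level_m,
        cluster_size_j=cluster_size_j,
        n_elements=n_elements,
        element_px=element_px,
        px_per_deg=px_per_deg,
        parity=parity,
        mean_luminance=mean_luminance,
    )
    return make_battenberg(spec)


def matching_spec(mode: str, level_m: float, **geometry) -> BattenbergSpec:
    """BattenbergSpec of a matching stimulus (component contrasts by mode)."""
    if mode == "single":
        a, b = level_m, 0.0
    elif mode == "dual":
        a, b = level_m, level_m
    else:
        raise ValueError(f"mode must be 'single' or 'dual', got {mode!r}")
    return BattenbergSpec(contrast_A=a, contrast_B=b, **geometry)


# ---------------------------------------------------------------------------
# I/O: linear PNG (mean mapped to mid-grey) or float .npy, with a JSON sidecar


def save_image(
    img: LuminanceImage,
    path: str | Path,
    spec: BattenbergSpec | None = None,
    bits: int = 8,
) -> None:
    """Write a luminance image to PNG (8/16-bit linear) or .npy.

    PNG export is linear: mean luminance maps to mid-grey and 2x mean maps
    to white, so contrasts up to 100% are representable without clipping.
    A plain-text JSON sidecar (``<path>.json``) records the sampling density
    and, when given, the generating spec.
    """
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, img.pixels)
    elif path.suffix == ".png":
        from PIL import Image

        if bits not in (8, 16):
            raise ValueError("bits must be 8 or 16")
        maxval = 2**bits - 1
        scaled = img.pixels / (2.0 * img.pixels.mean()) * maxval
        scaled = np.clip(np.rint(scaled), 0, maxval)
        if bits == 8:
            Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)
        else:
            Image.fromarray(scaled.astype(np.uint16)).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    sidecar = {"px_per_deg": img.px_per_deg, "mean_luminance": img.mean_luminance}
    if spec is not None:
        sidecar["spec"] = {
            "contrast_A": spec.contrast_A,
            "contrast_B": spec.contrast_B,
            "cluster_size_j": spec.cluster_size_j,
            "parity": spec.parity,
            "n_elements": spec.n_elements,
            "element_px": spec.element_px,
        }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_image(path: str | Path) -> LuminanceImage:
    """Read a PNG or .npy image back into normalized luminance.

    PNG values are rescaled so the array mean is the sidecar's mean
    luminance (default 1.0 when no sidecar is present).
    """
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    px_per_deg = float(meta.get("px_per_deg", 48.0))
    if path.suffix == ".npy":
        return LuminanceImage(pixels=np.load(path), px_per_deg=px_per_deg)
    from PIL import Image

    raw = np.asarray(Image.open(path), dtype=float)
    if raw.ndim == 3:  # collapse RGB(A) to grayscale
        raw = raw[..., :3].mean(axis=-1)
    mean_lum = float(meta.get("mean_luminance", 1.0))
    if raw.mean() <= 0:
        raise ValueError("image has non-positive mean; cannot normalize")
    pixels = raw / raw.mean() * mean_lum
    return LuminanceImage(pixels=pixels, px_per_deg=px_per_deg)
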