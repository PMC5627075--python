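"""Log-Gabor spatial-filtering front end.

Converts a luminance image into a map of band-pass filter responses, the
model of an early oriented visual channel.  The transfer function is
Gaussian in log spatial frequency (so it has exactly zero DC response) and
Gaussian in orientation around the preferred frequency direction.  The
kernel is single-sided in the frequency domain with a factor of 2, i.e. an
analytic filter: the real part of the spatial response is the cosine-phase
filter output, the imaginary part the sine-phase output, and the complex
modulus the quadrature-pair (local energy) envelope.

Normalization contract: a full-field grating at the filter's preferred
frequency and orientation with Michelson contrast C (%) produces a response
map whose peak value is C.  Filter outputs are therefore in the same
percent-contrast units as Weber contrast maps and can be fed to any
map-level model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ContrastMap
from .stimulus import LuminanceImage

__all__ = ["FilterParams", "make_log_gabor", "filter_contrast_map"]

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FilterParams:
    """Log-Gabor channel parameters.

    center_freq_cpd : peak spatial frequency, cycles/deg (default 2.4, the
        Battenberg carrier).
    bandwidth_oct : full bandwidth at half magnitude, octaves.
    orientation_deg : grating (bar) orientation the filter prefers;
        0 = horizontal bars, i.e. a vertical frequency vector.
    angular_hwhh_deg : angular half-width at half height of the orientation
        tuning, degrees.
    phase : 'cosine', 'sine' (rectified outputs) or 'quadrature' (modulus).
    """

    center_freq_cpd: float = 2.4
    bandwidth_oct: float = 1.6
    orientation_deg: float = 0.0
    angular_hwhh_deg: float = 25.0
    phase: str = "cosine"

    def __post_init__(self) -> None:
        if self.center_freq_cpd <= 0:
            raise ValueError("center_freq_cpd must be positive")
        if self.bandwidth_oct <= 0 or self.angular_hwhh_deg <= 0:
            raise ValueError("bandwidth and angular spread must be positive")
        if self.phase not in ("cosine", "sine", "quadrature"):
            raise ValueError(f"unknown phase {self.phase!r}")


def make_log_gabor(
    shape: tuple[int, int],
    px_per_deg: float,
    params: FilterParams | None = None,
) -> np.ndarray:
    """Frequency-domain log-Gabor transfer function for an image of ``shape``.

    Returns a real array in unshifted FFT layout, single-sided (energy only
    around the +preferred frequency direction) and scaled by 2, so that
    ``ifft2(fft2(signal) * kernel)`` is the analytic (complex) response.
    The gain at the preferred frequency/orientation is 2 x 1, which makes a
    matched unit-contrast grating produce a unit-peak cosine response.
    """
    params = params or FilterParams()
    nyquist = px_per_deg / 2.0
    if params.center_freq_cpd >= nyquist:
        raise ValueError(
            f"center frequency {params.center_freq_cpd} c/deg is at or above "
            f"the Nyquist frequency {nyquist} c/deg"
        )
    h, w = shape
    fy = np.fft.fftfreq(h, d=1.0 / px_per_deg)[:, None]
    fx = np.fft.fftfreq(w, d=1.0 / px_per_deg)[None, :]
    f = np.hypot(fy, fx)

    # Radial term: Gaussian in ln(f), zero at DC by construction.
    sigma_ln = params.bandwidth_oct * np.log(2.0) / (2.0 * _SQRT_2LN2)
    with np.errstate(divide="ignore"):
        lnr = np.log(np.where(f > 0, f, 1.0) / params.center_freq_cpd)
    radial = np.exp(-(lnr**2) / (2.0 * sigma_ln**2))
    radial[f == 0] = 0.0

    # Angular term: Gaussian around the +preferred frequency direction only
    # (single-sided).  Bar orientation theta means frequency direction
    # theta + 90 deg.
    pref = np.deg2rad(params.orientation_deg + 90.0)
    sigma_theta = np.deg2rad(params.angular_hwhh_deg) / _SQRT_2LN2
    dtheta = np.arctan2(fy, fx) - pref
    dtheta = np.arctan2(np.sin(dtheta), np.cos(dtheta))  # wrap to [-pi, pi]
    angular = np.exp(-(dtheta**2) / (2.0 * sigma_theta**2))

    return 2.0 * radial * angular


def filter_contrast_map(
    img: LuminanceImage,
    params: FilterParams | None = None,
    kernel: np.ndarray | None = None,
    pad: bool = True,
) -> ContrastMap:
    """Filter a luminance image into a contrast map (percent units).

    The image is converted to signed percent Weber contrast
    100*(L/L_mean - 1), convolved with the log-Gabor via the FFT, and
    reduced per the phase mode: 'cosine'/'sine' outputs are full-wave
    rectified, 'quadrature' returns the modulus of the analytic response.

    With ``pad=True`` (default) the signal is embedded in a field of twice
    the size at mean luminance before the (circular) convolution, so
    wraparound from opposite borders cannot reach the stimulus; the map is
    cropped back to the image size.  ``pad=False`` is exact for stimuli that
    are genuinely periodic in the frame.
    """
    params = params or FilterParams()
    px = img.pixels
    mean = px.mean()
    if mean <= 0:
        raise ValueError("mean luminance must be positive")
    signal = 100.0 * (px / mean - 1.0)
    h, w = signal.shape
    if pad:
        padded = np.zeros((2 * h, 2 * w))
        y0, x0 = h // 2, w // 2
        padded[y0 : y0 + h, x0 : x0 + w] = signal
        work = padded
    else:
        y0 = x0 = 0
        work = signal
    if kernel is None:
        kernel = make_log_gabor(work.shape, img.px_per_deg, params)
    elif kernel.shape != work.shape:
        raise ValueError(
            f"kernel shape {kernel.shape} does not match working shape {work.shape}"
        )
    resp = np.fft.ifft2(np.fft.fft2(work) * kernel)
    resp = resp[y0 : y0 + h, x0 : x0 + w]
    if params.phase == "cosine":
        values = np.abs(resp.real)
    elif params.phase == "sine":
        values = np.abs(resp.imag)
    else:
        values = np.abs(resp)
    return ContrastMap(values, "filter_response")
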