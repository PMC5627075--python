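# Methods

## Stimuli

Battenberg patterns are built from a horizontal sine-wave carrier
multiplied by a full-wave-rectified vertical sine wave of half the carrier
frequency. At the defaults (20 × 20 elements of 20 × 20 px, 48 px/deg) the
carrier is 2.4 c/deg and each element holds exactly one carrier cycle
windowed by one half-cycle of the rectified envelope. Two constructional
choices are under-determined by that description and are fixed here:

- **Carrier phase.** Sine phase with zero crossings at element boundaries,
  so every element is a complete, self-contained cycle and all element
  boundaries sit exactly at mean luminance. Only within-element appearance
  depends on this; the rectified envelope forces zero contrast at vertical
  element edges regardless.
- **j = 8 tiling.** A cluster size of 8 does not divide the 20-element
  grid. The mask is built on a 24-element virtual grid and centre-cropped,
  leaving truncated 6-element half-clusters at the borders. This preserves
  the overall stimulus size while giving interior clusters the full 8 × 8
  extent. It is a choice, not a constraint of the stimulus family, and
  `checker_mask` treats a non-divisible j as an error unless truncation is
  requested explicitly.

At integer pixel coordinates the carrier attains ±1 exactly (element size
divisible by 4) and the per-column carrier mean is exactly zero, so the
image mean equals the nominal mean luminance to accumulation precision and
the whole-image Michelson contrast equals max(A, B). Images are
double-precision linear luminance normalized to mean 1.0; PNG export maps
mean to mid-grey with a linear (gamma = 1) scale. Presentation timing
(100 ms duration, 400 ms ISI) is carried as metadata only — no model
component depends on time.

## Contrast models

Local contrast is the rectified Weber fraction 100·|L_i − L̄|/L̄ (percent),
with L̄ the whole-image mean. All transducer arithmetic uses percent units:
the canonical exponents were estimated on percent contrast and the
quantities C^2.4 are not unit-invariant. Rectification before
exponentiation is required for real non-integer powers; for the default
q = 2 the choice of signed vs rectified denominator is immaterial, and for
the q = 1.6 variant we rectify.

Model responses, for a contrast map {c_i} (two entries A, B in toy form):

| model  | response |
|--------|----------|
| max    | max(c_i) |
| linsum | Σ c_i |
| energy | Σ c_i² |
| lf     | Σ c_i^p/(z + c_i^q), optionally (Σ t_i^k)^{1/k} |
| ms     | Σ(c_i^p) / (z + Σ(c_i^q)) |

Defaults p = 2.4, q = 2.0, z = 1, with p > q enforced (otherwise the
response saturates and the matching problem has no increasing inverse).
The gain-control (ms) response pools excitation and suppression separately
over the whole map before dividing; this cures the area-dependence of sum
and energy (for a uniform map of level c the response tends to c^{p−q} as
area grows) and produces the paradox: adding a weak component to a strong
one can lower the response, because its denominator (suppressive)
contribution outweighs its numerator contribution. The toy response at the
400-element grid is recovered exactly from the element-level map when z is
scaled by the 200 elements per component; with z = 1 the two differ by
~1% at the 8% pedestal, which moves PSEs by ≲ 0.15 dB.

The saturation constant matters only near threshold. Measured on the
default grid (B = 8%, both match modes), setting z = 0 moves toy PSEs by at
most 0.16 dB (largest at A ≤ 4%, where the denominator sum is smallest) —
negligible against the ≥ 0.8 dB differences that separate models, though
not strictly below 0.1 dB. Swapping the exponents to (p, q) = (2.0, 1.6)
moves PSEs by at most 0.47 dB on the same grid.

## Spatial filtering

The optional front end is a single log-Gabor channel tuned to the carrier:
Gaussian in log frequency (default bandwidth 1.6 octaves full width at
half magnitude), Gaussian in orientation (default ±25° half-width at
half-height), zero DC by construction. These are conventional V1-like
values; the source description of the filter defers its parameters to
earlier detection work, so they are exposed in `FilterParams` and the
cluster-size result below is qualitative with respect to them. The kernel
is single-sided in frequency and doubled (an analytic filter), so the real
part of the complex response is the cosine-phase output, the imaginary
part the sine-phase output and the modulus the quadrature envelope;
cosine/sine outputs are full-wave rectified before entering the models.
It is normalized so a matched full-field grating of Michelson contrast C%
yields a peak response of C — filter outputs share the percent scale of
Weber maps. Convolution is circular via the FFT on an image padded to
twice its size with mean luminance, which keeps wraparound from reaching
the stimulus; tests that need exact values use unpadded, frame-periodic
gratings.

Because the filter footprint spans more than one element, at j = 1 it sums
indiscriminately across A/B boundaries and the filtered gain-control model
behaves like the linear-sum model (measured: filtered curves are within
~0.6 dB RMS of the linear-sum toy curves and ~3 dB from the gain-control
toy curves); as j grows the boundaries become rare, and by j = 8 the
ordering has reversed. Unfiltered pixelwise application tracks the toy
model within ~0.1 dB everywhere.

## PSE prediction

The predicted PSE is the match level m at which the model's response to
the matching stimulus equals its response to the test. All match-family
maps scale linearly in m (Weber maps and linear-filter outputs are
homogeneous of degree 1 in contrast), so a unit-level map is computed once
and the level dependence reduces to closed forms (power sums) for the
separable models and a vectorized map pass for the summed transducer.
Monotonicity of the match response in m is verified numerically on a
33-point log grid before each solve. Bisection runs in log contrast on
[10⁻⁶, 200] % to a relative response tolerance of 10⁻⁹ or 60 iterations;
the bracket deliberately extends beyond the physical 100% so that badly
failing models (the summed transducer predicts ≈ 30% for a (4, 8) test)
still converge, with solutions above 100% flagged. A match family that
cannot reach the test response returns a non-converged result with
diagnostics rather than an extrapolation. The default test grid of 'A'
contrasts is {0, 0.5, 1, 2, 4, 8, 16, 32} % — octave-spaced over the
stated 0–32% range, since the exact experimental levels are not recorded.

## Simulated observer

The decision stage is late additive Gaussian noise on the model response:
the observer reports whichever interval's noisy response is larger. No
particular noise model is implied by the matching data (only the PSE, not
the slope, is compared with theory); the default noise of 5% of the test
response makes the simulated psychometric spread and staircase trial
counts resemble typical matching data. A pair of randomly interleaved
1-up-1-down staircases starts ±6 dB around max(A, B) and steps 3 dB until
a staircase's first reversal, then 1.5 dB, terminating after 12 reversals
each — under the default noise this yields a trial-count distribution
centred near 42 per repetition. Step sizes and starting levels are
reconstructions; only the 12-reversal termination and the pairing are
fixed by the procedure being emulated. Each repetition's choices are fit
by a two-parameter maximum-likelihood cumulative log-Gaussian
Φ((log m − log α)/σ) — no lapse parameters — with degenerate data (one
choice category, or a single level) flagged rather than fitted, and the
PSE estimate is the mean fitted α over repetitions (default 4). The
closed-loop oracle — simulated estimates converging on the analytic PSEs
as noise shrinks — is tested at 2% decision noise, where every default
grid point in both match modes recovers its analytic PSE within 0.5 dB.

## Model comparison

PSE errors are expressed in dB as 20·log₁₀(pred/ref) and aggregated as the
RMS over conditions; 6.02 dB is a factor of two. The dB convention is a
declared assumption (it is the standard one for contrast). Reference PSE
tables are either simulated or supplied by the user as CSV
(`A, mode, j, pse`); no experimental PSE values are bundled, since those
exist publicly only as figure points.

## Problem sizes and limitations

The test suite and the acceptance script run on the full default stimulus
geometry (400 × 400 px images, 800 × 800 padded FFTs) and the default
8-point contrast grid; simulated experiments use 4 repetitions of paired
12-reversal staircases per condition. The synthetic observer shares the
response machinery of the models it is used to test — closed-loop
recovery therefore validates the staircase/fitting pipeline, not the
models themselves, and says nothing about idiosyncrasies of human
observers (individual differences, response strategies, asymmetric
excitatory/inhibitory pooling extents). Only a single log-Gabor scale and
orientation is implemented — no multi-band decomposition for natural
images — and model parameters are never fitted to data: every prediction
in this package is parameter-free given (p, q, z).
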