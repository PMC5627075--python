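# battenberg

How should the *global* contrast of an image be computed? Widely used
summary statistics — Michelson contrast, RMS contrast, contrast energy, the
maximum local contrast — all aggregate local contrast in ways that turn out
to disagree with human perception. `battenberg` is a toolkit for studying
this question with the stimulus class built for it: **Battenberg patterns**,
checkerboards of grating micro-patterns in which two interdigitated
components ('A' and 'B') carry independently controlled contrasts, with a
cluster-size parameter *j* setting the spatial grain of the interdigitation.

The package is aimed at visual psychophysicists and image-processing
researchers who want a perceptually grounded global-contrast metric. It
provides:

- **Stimulus synthesis** (`battenberg.stimulus`): deterministic Battenberg
  test and matching stimuli (2.4 c/deg carrier, 20×20 single-cycle
  elements at the defaults), plus PNG/float I/O.
- **Contrast models** (`battenberg.metrics`): Michelson, RMS, MAX, sum,
  average, energy; the summed Legge–Foley transducer
  `Σ C^p/(z + C^q)` (optionally with Minkowski summation); and the
  wide-field contrast gain-control response

  ```
  R = Σ(C^p) / (z + Σ(C^q)),    p = 2.4, q = 2.0, z = 1
  ```

  in which excitation (numerator) and suppression (denominator) are each
  pooled over the whole image *before* the division. C is local contrast in
  percent. Every model runs in "toy" form on the two component contrasts
  (A, B), or over element-level or pixel-level contrast maps.
- **Spatial filtering** (`battenberg.filtering`): an optional log-Gabor
  front end (V1-like channel: Gaussian in log frequency and orientation,
  zero DC) whose rectified/quadrature output feeds the same models.
- **Matching predictions** (`battenberg.matching`): the point of subjective
  equality (PSE) for a 'single' (one component at level m) or 'dual' (both
  components at m) matching stimulus — the level at which the model
  responds equally to match and test — solved by log-contrast bisection
  with no free parameters.
- **Simulated observers** (`battenberg.observer`): a late-Gaussian-noise
  2IFC decision stage, interleaved 1-up-1-down staircases (12 reversals,
  ≈ 42 trials per repetition), maximum-likelihood cumulative log-Gaussian
  psychometric fits, and repetition-averaged PSE estimates.
- **Model comparison** (`battenberg.evaluation`): RMS error in dB
  (20·log₁₀ of the PSE ratio) against simulated or user-supplied reference
  PSE tables, rankings and matching-curve plots.

The scientific centrepiece is a *paradox*: adding a low-contrast component
to a higher-contrast pattern can **reduce** perceived global contrast. Of
all the models above, only the gain-control response reproduces it — the
added component contributes more suppression than excitation over a
critical contrast range.

## Worked example

```python
from battenberg import MatchingCondition, predict_pse

for A in (0, 4, 16):
    res = predict_pse(MatchingCondition(test_A=A, test_B=8.0,
                                        match_mode="single", model_id="ms"))
    print(f"A={A:>2}%  B=8%  ->  PSE = {res.pse:.3f}%")
```

prints

```
A= 0%  B=8%  ->  PSE = 8.000%
A= 4%  B=8%  ->  PSE = 7.187%
A=16%  B=8%  ->  PSE = 14.197%
```

With A = 0 the test is itself a member of the single-component match
family, so the match is exact at the 8% pedestal. Adding a 4% component
*lowers* the matched contrast to 7.19% — below the pedestal — and a 16%
component is matched by only 14.2%, below the component itself: the
paradox, in both limbs. A MAX or RMS model would put both values at
max(A, B). The same prediction can be run per-pixel on the rendered images
(`granularity="pixelwise"`), and with the log-Gabor front end
(`filtered=True`), which at j = 1 blurs the A/B boundaries and makes the
gain-control model behave like the (unsuccessful) linear-sum model —
removing the filter restores the prediction.

The same things are available from the shell:

```bash
battenberg generate --A 32 --B 8 --j 2 --out stim.png
battenberg metric --image stim.png
battenberg predict --model ms --mode single --out curve.csv
battenberg simulate --model ms --A 4 --seed 1
battenberg compare --reference curve.csv --models max,linsum,energy,lf,ms --out report/
```

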