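"""Simulated two-interval contrast-matching experiments.

A stochastic observer chooses, on each trial, which of the test and
matching stimuli appears higher in global contrast: the model response to
each stimulus is perturbed by independent zero-mean Gaussian decision noise
and the larger noisy response wins.  A pair of interleaved 1-up-1-down
staircases drives the matching level (each terminating after 12 reversals,
~42 trials per repetition in total), a two-parameter cumulative
log-Gaussian is fitted to the resulting choice data by maximum likelihood,
and its location parameter alpha is the estimated PSE.  Repetitions are
averaged, as in the matching experiments this emulates.

The closed loop — simulate, fit, average — should recover the analytic PSE
from :mod:`battenberg.matching` as noise shrinks and trials grow, which is
the module's central oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .matching import MatchEngine, MatchingCondition, stimulus_response

__all__ = [
    "StaircaseConfig",
    "TrialRecord",
    "PsychometricFit",
    "simulate_choice",
    "run_staircase",
    "fit_psychometric",
    "estimate_pse",
    "trials_to_frame",
]

#: Default decision noise, as a fraction of the test response.  Chosen so a
#: simulated psychometric function has a spread of a few tenths of a log
#: unit — steep enough that staircases hover near the PSE, shallow enough
#: that adjacent staircase levels get graded choice probabilities.
DEFAULT_NOISE_FRACTION = 0.05


@dataclass(frozen=True)
class StaircaseConfig:
    """1-up-1-down staircase settings.

    Two interleaved staircases share the trial stream, starting above and
    below ``initial_level`` (by ``start_offset_db``).  Steps are
    ``step_db_initial`` until a staircase's first reversal, then ``step_db``;
    each staircase stops after ``n_reversals_to_terminate`` reversals.
    Levels are in percent contrast, steps in dB (20*log10 units).
    """

    n_reversals_to_terminate: int = 12
    initial_level: float | None = None  # None: max(test_A, test_B)
    step_db_initial: float = 3.0
    step_db: float = 1.5
    start_offset_db: float = 6.0
    n_interleaved: int = 2
    level_floor: float = 1e-3
    level_ceiling: float = 200.0

    def __post_init__(self) -> None:
        if self.step_db <= 0 or self.step_db_initial <= 0:
            raise ValueError("staircase steps must be positive dB")
        if self.n_reversals_to_terminate < 1:
            raise ValueError("need a positive reversal count to terminate")
        if self.n_interleaved < 1:
            raise ValueError("need at least one staircase")


@dataclass(frozen=True)
class TrialRecord:
    """One 2IFC trial: the match level shown and the observer's choice."""

    trial: int
    staircase_id: int
    match_level: float
    interval_order: int  # 0: test first, 1: match first
    observer_choice: str  # 'test' or 'match' judged higher in contrast
    reversal: bool

    def __post_init__(self) -> None:
        if self.match_level <= 0:
            raise ValueError("match level must be positive")
        if self.observer_choice not in ("test", "match"):
            raise ValueError(f"bad choice {self.observer_choice!r}")


@dataclass(frozen=True)
class PsychometricFit:
    """Two-parameter cumulative log-Gaussian fit (no lapse parameters).

    ``alpha`` is the PSE (%); ``sigma_log`` the spread in log10-contrast
    units.  ``converged`` is False for degenerate data (fewer than two
    distinct levels, or only one choice category present) — no silent
    defaults are returned in that case.
    """

    alpha: float
    sigma_log: float
    loglik: float
    n_trials: int
    converged: bool


def simulate_choice(
    test_response: float,
    match_response: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> str:
    """Late-noise 2IFC decision: the larger noisy response is chosen.

    Returns 'match' iff R_match + e_m > R_test + e_t, with e ~ N(0, noise_sd)
    independent per interval.  noise_sd = 0 gives the deterministic rule
    (ties resolved at chance).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        if match_response == test_response:
            return "match" if rng.random() < 0.5 else "test"
        return "match" if match_response > test_response else "test"
    e_t, e_m = rng.normal(0.0, noise_sd, size=2)
    return "match" if match_response + e_m > test_response + e_t else "test"


class _Staircase:
    def __init__(self, level: float, cfg: StaircaseConfig):
        self.level = level
        self.cfg = cfg
        self.reversals = 0
        self._last_direction = 0  # +1 up, -1 down

    @property
    def active(self) -> bool:
        return self.reversals < self.cfg.n_reversals_to_terminate

    def update(self, choice: str) -> bool:
        """Apply the 1-up-1-down rule; returns True if this was a reversal."""
        direction = -1 if choice == "match" else +1
        reversal = self._last_direction != 0 and direction != self._last_direction
        if reversal:
            self.reversals += 1
        self._last_direction = direction
        step = self.cfg.step_db_initial if self.reversals == 0 else self.cfg.step_db
        self.level *= 10.0 ** (direction * step / 20.0)
        self.level = min(max(self.level, self.cfg.level_floor), self.cfg.level_ceiling)
        return reversal


def run_staircase(
    cond: MatchingCondition,
    noise_sd: float | None = None,
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
    engine: MatchEngine | None = None,
) -> list[TrialRecord]:
    """Simulate one repetition: interleaved 1-up-1-down staircases to 12
    reversals each.

    A 'match' choice (match judged higher) lowers that staircase's level; a
    'test' choice raises it, so levels converge on the 50% point — the PSE.
    On each trial one of the still-active staircases is drawn at random.
    ``noise_sd`` is in model-response units; None uses
    ``DEFAULT_NOISE_FRACTION`` of the test response.
    """
    cfg = config or StaircaseConfig()
    rng = np.random.default_rng(rng)
    engine = engine or MatchEngine(cond)
    r_test = stimulus_response(cond)
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_FRACTION * r_test
    start = cfg.initial_level
    if start is None:
        start = max(cond.test_A, cond.test_B)
        if start <= 0:
            raise ValueError("cannot infer a starting level from a blank test")
    offsets = np.linspace(-1.0, 1.0, cfg.n_interleaved) if cfg.n_interleaved > 1 else [0.0]
    stairs = [
        _Staircase(start * 10.0 ** (o * cfg.start_offset_db / 20.0), cfg)
        for o in offsets
    ]
    records: list[TrialRecord] = []
    t = 0
    while any(s.active for s in stairs):
        active = [i for i, s in enumerate(stairs) if s.active]
        i = int(rng.choice(active))
        s = stairs[i]
        level = s.level
        r_match = engine.match_response(level)
        choice = simulate_choice(r_test, r_match, noise_sd, rng)
        reversal = s.update(choice)
        records.append(
            TrialRecord(
                trial=t,
                staircase_id=i,
                match_level=level,
                interval_order=int(rng.integers(2)),
                observer_choice=choice,
                reversal=reversal,
            )
        )
        t += 1
    return records


def _nll(theta, log_m, y):
    mu, log_sigma = theta
    sigma = np.exp(log_sigma)
    p = norm.cdf((log_m - mu) / sigma)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def fit_psychometric(trials: list[TrialRecord]) -> PsychometricFit:
    """Maximum-likelihood cumulative log-Gaussian fit to the choice data.

    Fits P(choose match | level m) = Phi((log10 m - log10 alpha)/sigma) by
    Bernoulli likelihood over all trials.  Data with fewer than two distinct
    levels or with only one choice category are flagged degenerate
    (``converged=False``) rather than fitted.
    """
    if not trials:
        raise ValueError("no trials to fit")
    m = np.array([t.match_level for t in trials])
    y = np.array([1.0 if t.observer_choice == "match" else 0.0 for t in trials])
    n = len(trials)
    if len(np.unique(m)) < 2 or y.min() == y.max():
        return PsychometricFit(float("nan"), float("nan"), float("nan"), n, False)
    log_m = np.log10(m)
    x0 = np.array([np.median(log_m), np.log(0.1)])
    best = None
    for scale in (1.0, 0.3, 3.0):
        res = minimize(
            _nll,
            x0 + [0.0, np.log(scale)],
            args=(log_m, y),
            method="Nelder-Mead",
            options=dict(xatol=1e-7, fatol=1e-10, maxiter=2000),
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x
    return PsychometricFit(
        alpha=float(10.0**mu),
        sigma_log=float(np.exp(log_sigma)),
        loglik=float(-best.fun),
        n_trials=n,
        converged=bool(best.success),
    )


def estimate_pse(
    cond: MatchingCondition,
    n_repetitions: int = 4,
    noise_sd: float | None = None,
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Experimental PSE estimate: mean fitted alpha over repetitions.

    Runs ``n_repetitions`` independent staircase repetitions, fits each
    repetition's psychometric function, and averages the fitted PSEs.
    Degenerate repetitions are excluded; if every repetition is degenerate a
    RuntimeError is raised rather than returning a default.
    """
    rng = np.random.default_rng(rng)
    engine = MatchEngine(cond)
    alphas = []
    for _ in range(n_repetitions):
        trials = run_staircase(cond, noise_sd=noise_sd, config=config, rng=rng, engine=engine)
        fit = fit_psychometric(trials)
        if fit.converged:
            alphas.append(fit.alpha)
    if not alphas:
        raise RuntimeError(
            "all repetitions produced degenerate psychometric data; "
            "increase noise or trial counts"
        )
    return float(np.mean(alphas))


def trials_to_frame(trials: list[TrialRecord]):
    """Trial log as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        dict(
            trial=[t.trial for t in trials],
            staircase=[t.staircase_id for t in trials],
            level_pct=[t.match_level for t in trials],
            interval_order=[t.interval_order for t in trials],
            choice=[t.observer_choice for t in trials],
            reversal_flag=[t.reversal for t in trials],
        )
    )
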