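"""Model comparison in dB and figure-style outputs.

PSEs are compared on a log-contrast axis: the error between a predicted and
a reference PSE is 20*log10(pred/ref) dB, and a model's overall score is
the RMS of that error over the condition set.  The reference table can come
from the simulated-observer engine or be supplied by the user as CSV (e.g.
experimentally measured PSEs), with columns ``A, mode, j, pse``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matching import MatchingCondition, matching_curve

__all__ = [
    "to_db",
    "from_db",
    "rms_error_db",
    "ModelComparison",
    "compare_models",
    "plot_matching_curves",
]

_KEYS = ["A", "mode", "j"]


def to_db(contrast):
    """Contrast (%) to dB: 20*log10(C)."""
    c = np.asarray(contrast, dtype=float)
    if np.any(c <= 0):
        raise ValueError("contrast must be positive to express in dB")
    out = 20.0 * np.log10(c)
    return float(out) if np.isscalar(contrast) else out


def from_db(db):
    """Inverse of :func:`to_db`."""
    out = 10.0 ** (np.asarray(db, dtype=float) / 20.0)
    return float(out) if np.isscalar(db) else out


def rms_error_db(pred, ref) -> float:
    """RMS over conditions of the dB ratio between predicted and reference PSEs.

    Accepts aligned 1-D arrays, or DataFrames carrying ``A, mode, j, pse``
    columns, which are merged on the condition keys before comparison.
    """
    if isinstance(pred, pd.DataFrame) or isinstance(ref, pd.DataFrame):
        merged = pd.merge(
            pred[_KEYS + ["pse"]],
            ref[_KEYS + ["pse"]],
            on=_KEYS,
            suffixes=("_pred", "_ref"),
            how="inner",
        )
        if len(merged) != len(pred) or len(merged) != len(ref):
            raise ValueError("prediction and reference tables do not align")
        p, r = merged["pse_pred"].to_numpy(), merged["pse_ref"].to_numpy()
    else:
        p, r = np.asarray(pred, float), np.asarray(ref, float)
        if p.shape != r.shape:
            raise ValueError(f"misaligned tables: {p.shape} vs {r.shape}")
    if p.size == 0:
        raise ValueError("empty PSE tables")
    if np.any(p <= 0) or np.any(r <= 0):
        raise ValueError("PSEs must be positive")
    return float(np.sqrt(np.mean((20.0 * np.log10(p / r)) ** 2)))


@dataclass(frozen=True)
class ModelComparison:
    """Per-model matching curves, dB errors against the reference, ranking."""

    table: pd.DataFrame  # tidy: A, mode, j, model, pse (+ reference rows)
    rms_db: dict
    ranking: tuple

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                model=list(self.ranking),
                rms_error_db=[self.rms_db[m] for m in self.ranking],
                rank=np.arange(1, len(self.ranking) + 1),
            )
        )


def compare_models(
    reference: pd.DataFrame,
    models=("max", "linsum", "energy", "lf", "ms"),
    base_cond: MatchingCondition | None = None,
) -> ModelComparison:
    """Run every model over the reference's conditions and rank by RMS dB error.

    ``reference`` needs columns ``A, mode, j, pse``.  ``base_cond`` carries
    the pipeline options (granularity, filtering, parameters, geometry)
    shared by all models; its test/model fields are overridden per row.
    """
    ref = reference.copy()
    missing = [k for k in _KEYS + ["pse"] if k not in ref.columns]
    if missing:
        raise ValueError(f"reference table lacks columns {missing}")
    base = base_cond or MatchingCondition(test_A=0.0)
    frames, rms = [], {}
    for model in models:
        preds = []
        for (mode, j), grp in ref.groupby(["mode", "j"], sort=False):
            cond = replace(
                base, model_id=model, match_mode=mode, cluster_size_j=int(j)
            )
            preds.append(matching_curve(cond, grp["A"].to_numpy()))
        pred = pd.concat(preds, ignore_index=True)
        rms[model] = rms_error_db(pred, ref)
        frames.append(pred)
    ranking = tuple(sorted(rms, key=rms.get))
    return ModelComparison(
        table=pd.concat(frames, ignore_index=True), rms_db=rms, ranking=ranking
    )


def plot_matching_curves(
    curves: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    pedestal: float = 8.0,
    ax=None,
):
    """Matching curves on log axes with the pedestal and unit-slope guides.

    Layout follows the conventional presentation of matching data: log
    abscissa (test 'A' contrast), log ordinate (matching contrast), a
    horizontal dashed line at the fixed pedestal and an oblique dashed line
    of unit slope where the 'A' component dominates.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for model, grp in curves.groupby("model"):
        grp = grp.sort_values("A")
        pos = grp[grp["A"] > 0]
        ax.plot(pos["A"], pos["pse"], label=str(model))
    if reference is not None:
        pos = reference[reference["A"] > 0]
        ax.plot(pos["A"], pos["pse"], "ko", mfc="none", label="reference")
    a = curves["A"].to_numpy()
    a_pos = a[a > 0]
    if a_pos.size:
        ax.axhline(pedestal, ls="--", c="k", lw=0.8)
        span = np.array([a_pos.min(), a_pos.max()])
        ax.plot(span, span, ls="--", c="k", lw=0.8)
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("test 'A' contrast (%)")
    ax.set_ylabel("matching contrast (%)")
    ax.legend(fontsize=8)
    return ax
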