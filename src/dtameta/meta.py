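"""Diagnostic test accuracy meta-analysis.

Per-study indices (sensitivity, specificity, likelihood ratios, diagnostic
odds ratio) are computed from 2x2 tables, with a +0.5 continuity correction
applied to all four cells of any table containing a zero so the log-scale
ratios stay finite.  Pooling follows the conventions of classical DTA
meta-analysis software:

* sensitivity and specificity pool as aggregate proportions
  (sum of numerators / sum of denominators over the raw counts), with a
  binomial normal-approximation CI and Cochran's Q / I-squared computed with
  study-specific binomial variances;
* PLR, NLR and DOR pool on the natural-log scale, either fixed-effect
  (inverse variance) or DerSimonian-Laird random effects, with the
  moment estimator tau^2 = max(0, (Q - df) / (sum(w) - sum(w^2)/sum(w)))
  and symmetric-on-log-scale 95% CIs exponentiated back.

Variances of the log ratios come from the delta method:
var(ln DOR) = 1/TP + 1/FP + 1/FN + 1/TN,
var(ln PLR) = 1/TP - 1/(TP+FN) + 1/FP - 1/(FP+TN),
var(ln NLR) = 1/FN - 1/(TP+FN) + 1/TN - 1/(FP+TN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classify import ConfusionTable

__all__ = [
    "StudyIndices",
    "PooledResult",
    "study_indices",
    "pool_proportion",
    "pool_log_ratio",
    "forest_data",
]

_Z95 = norm.ppf(0.975)

PROPORTION_INDICES = ("sens", "spec")
RATIO_INDICES = ("plr", "nlr", "dor")


@dataclass(frozen=True)
class StudyIndices:
    """One study's diagnostic indices with log-scale delta-method variances."""

    study_id: str
    sens: float
    spec: float
    plr: float
    nlr: float
    dor: float
    ln_plr: float
    ln_nlr: float
    ln_dor: float
    var_ln_plr: float
    var_ln_nlr: float
    var_ln_dor: float
    corrected: bool
    table: ConfusionTable

    def log_index(self, which: str) -> tuple[float, float]:
        """(log estimate, variance) for one of plr/nlr/dor."""
        if which not in RATIO_INDICES:
            raise ValueError(f"unknown ratio index {which!r}")
        return getattr(self, f"ln_{which}"), getattr(self, f"var_ln_{which}")


@dataclass(frozen=True)
class PooledResult:
    """A pooled diagnostic index with CI and heterogeneity statistics."""

    index_name: str
    estimate: float
    ci_low: float
    ci_high: float
    q_stat: float
    df: int
    tau2: float
    i2: float
    model: str

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("estimate outside its confidence interval")


def study_indices(table: ConfusionTable) -> StudyIndices:
    """Diagnostic indices for a single 2x2 table.

    A zero anywhere in the table triggers the +0.5 continuity correction on
    all four cells (ratio indices only; sens/spec pooling uses raw counts
    upstream, but this function's sens/spec reflect the corrected counts so
    that DOR = PLR/NLR holds exactly on one set of counts).
    """
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError(
            f"study {table.study_id!r}: a zero margin "
            f"({table.n_cases} cases, {table.n_controls} controls)"
        )
    corrected = table.has_zero_cell
    c = 0.5 if corrected else 0.0
    tp, fp, fn, tn = table.tp + c, table.fp + c, table.fn + c, table.tn + c
    n1, n0 = tp + fn, fp + tn
    sens, spec = tp / n1, tn / n0
    plr = sens / (1 - spec)
    nlr = (1 - sens) / spec
    dor = plr / nlr
    return StudyIndices(
        study_id=table.study_id,
        sens=sens,
        spec=spec,
        plr=plr,
        nlr=nlr,
        dor=dor,
        ln_plr=float(np.log(plr)),
        ln_nlr=float(np.log(nlr)),
        ln_dor=float(np.log(dor)),
        var_ln_plr=1 / tp - 1 / n1 + 1 / fp - 1 / n0,
        var_ln_nlr=1 / fn - 1 / n1 + 1 / tn - 1 / n0,
        var_ln_dor=1 / tp + 1 / fp + 1 / fn + 1 / tn,
        corrected=corrected,
        table=table,
    )


def pool_proportion(tables, which: str = "sens") -> PooledResult:
    """Pool sensitivity or specificity as an aggregate proportion.

    The point estimate is sum(numerators)/sum(denominators) over the raw
    (uncorrected) counts.  Cochran's Q uses inverse-variance weights with
    study-specific binomial variances p_i(1-p_i)/n_i around the aggregate
    estimate; I^2 = max(0, (Q - df)/Q) * 100.  The 95% CI is the binomial
    normal approximation on the aggregate, truncated to [0, 1].
    """
    if which not in PROPORTION_INDICES:
        raise ValueError(f"which must be one of {PROPORTION_INDICES}, got {which!r}")
    tables = list(tables)
    if not tables:
        raise ValueError("no studies to pool")
    if which == "sens":
        num = np.array([t.tp for t in tables], dtype=float)
        den = np.array([t.tp + t.fn for t in tables], dtype=float)
    else:
        num = np.array([t.tn for t in tables], dtype=float)
        den = np.array([t.tn + t.fp for t in tables], dtype=float)
    if (den == 0).any():
        raise ValueError("a study has an empty margin for this index")
    p_hat = num.sum() / den.sum()
    se = np.sqrt(p_hat * (1 - p_hat) / den.sum())
    if len(tables) == 1:
        return PooledResult(which, p_hat, max(0.0, p_hat - _Z95 * se),
                            min(1.0, p_hat + _Z95 * se), 0.0, 0, 0.0, 0.0, "fixed")
    # continuity-correct only the per-study variance terms where p_i is 0/1
    p_i = num / den
    p_var = np.where((num == 0) | (num == den), (num + 0.5) / (den + 1.0), p_i)
    var_i = p_var * (1 - p_var) / den
    w = 1.0 / var_i
    q = float(np.sum(w * (p_i - p_hat) ** 2))
    df = len(tables) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return PooledResult(
        index_name=which,
        estimate=float(p_hat),
        ci_low=float(max(0.0, p_hat - _Z95 * se)),
        ci_high=float(min(1.0, p_hat + _Z95 * se)),
        q_stat=q,
        df=df,
        tau2=0.0,
        i2=i2,
        model="fixed",
    )


def pool_log_ratio(studies, which: str = "dor", model: str = "random") -> PooledResult:
    """Pool PLR, NLR or DOR on the log scale.

    ``model="fixed"`` uses inverse-variance weights; ``model="random"`` adds
    the DerSimonian-Laird moment estimate of the between-study variance
    tau^2 to every study variance.  Q and I^2 always come from the
    fixed-weight stage.  Estimate and CI are exponentiated back to the ratio
    scale.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    studies = list(studies)
    if not studies:
        raise ValueError("no studies to pool")
    pairs = [s.log_index(which) for s in studies]
    y = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])
    if not np.isfinite(y).all() or not np.isfinite(v).all() or (v <= 0).any():
        raise ValueError(
            f"non-finite log {which} or invalid variance; continuity "
            "correction should have been applied upstream"
        )
    w = 1.0 / v
    fixed_est = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - fixed_est) ** 2))
    df = len(studies) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    if df == 0:
        tau2 = 0.0
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c)
    if model == "random":
        w_star = 1.0 / (v + tau2)
        est = float(np.sum(w_star * y) / np.sum(w_star))
        se = float(1.0 / np.sqrt(np.sum(w_star)))
    else:
        est = fixed_est
        se = float(1.0 / np.sqrt(np.sum(w)))
    return PooledResult(
        index_name=which,
        estimate=float(np.exp(est)),
        ci_low=float(np.exp(est - _Z95 * se)),
        ci_high=float(np.exp(est + _Z95 * se)),
        q_stat=q,
        df=df,
        tau2=tau2 if model == "random" else 0.0,
        i2=i2,
        model=model,
    )


def forest_data(studies, pooled: PooledResult) -> pd.DataFrame:
    """Plot-ready forest table: per-study rows sorted by effect size, then
    the pooled row.  Study weights are normalized to sum to 1.

    For ratio indices, per-study CIs are normal on the log scale with the
    random-effects weights implied by ``pooled.tau2``; for proportions, the
    binomial normal approximation on the corrected counts.
    """
    which = pooled.index_name
    rows = []
    if which in RATIO_INDICES:
        for s in studies:
            y, v = s.log_index(which)
            rows.append({
                "study_id": s.study_id,
                "estimate": float(np.exp(y)),
                "ci_low": float(np.exp(y - _Z95 * np.sqrt(v))),
                "ci_high": float(np.exp(y + _Z95 * np.sqrt(v))),
                "weight": 1.0 / (v + pooled.tau2),
            })
    else:
        for s in studies:
            t = s.table
            if which == "sens":
                num, den = t.tp, t.tp + t.fn
            else:
                num, den = t.tn, t.tn + t.fp
            p = num / den
            pv = (num + 0.5) / (den + 1.0) if num in (0, den) else p
            se = np.sqrt(pv * (1 - pv) / den)
            rows.append({
                "study_id": s.study_id,
                "estimate": p,
                "ci_low": max(0.0, p - _Z95 * se),
                "ci_high": min(1.0, p + _Z95 * se),
                "weight": den,
            })
    df = pd.DataFrame(rows)
    df["weight"] /= df["weight"].sum()
    df = df.sort_values("estimate", ascending=False, kind="mergesort")
    pooled_row = pd.DataFrame([{
        "study_id": f"pooled ({pooled.model})",
        "estimate": pooled.estimate,
        "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high,
        "weight": np.nan,
    }])
    return pd.concat([df, pooled_row], ignore_index=True)
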