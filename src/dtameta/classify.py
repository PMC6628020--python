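"""Univariate logistic classification of case status on expression.

Each study contributes one 2x2 diagnostic table per gene: a logistic
regression of case/control status on the gene's expression is fitted by
iteratively reweighted least squares, and every sample is classified by
thresholding its fitted probability (resubstitution — the classifier is
evaluated on its own training samples, matching a per-dataset design where
all samples of each cohort enter the table).

Complete separation is not an error here: the coefficients diverge but the
fitted probabilities pin to 0/1, so the confusion table — the only quantity
consumed downstream — is well defined.  The fit is simply capped and flagged
non-converged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "ConfusionTable",
    "fit_logistic",
    "confusion_from_fit",
    "confusion_table",
    "write_tables",
    "read_tables",
]

MAX_ITER = 50


@dataclass(frozen=True)
class LogisticFit:
    """Intercept/slope of a univariate logistic regression (log-odds units)."""

    beta0: float
    beta1: float
    converged: bool
    n_iter: int

    def predict_proba(self, x) -> np.ndarray:
        from scipy.special import expit

        return expit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ConfusionTable:
    """One study's TP/FP/FN/TN counts for a binary diagnostic test."""

    tp: int
    fp: int
    fn: int
    tn: int
    study_id: str = ""

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.tp, self.fp, self.fn, self.tn)


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        known = set(np.unique(y))
        if not known <= {"case", "control"}:
            raise ValueError(f"unknown labels: {sorted(known - {'case', 'control'})}")
        y = (y == "case").astype(float)
    else:
        y = y.astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("numeric labels must be 0/1")
    return y


def fit_logistic(expression, labels) -> LogisticFit:
    """ML fit of P(case) = expit(beta0 + beta1 * expression) by IRLS.

    Both classes must be present.  Under complete separation the iteration
    stops at the cap with ``converged=False``; the fitted probabilities
    (essentially 0/1) remain usable for classification.  A constant covariate
    yields ``beta1 = 0`` and fitted probability equal to the prevalence.
    """
    x = np.asarray(expression, dtype=float)
    y = _encode_labels(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("expression and labels differ in length")
    ncase = int(y.sum())
    if ncase == 0 or ncase == len(y):
        raise ValueError("both case and control samples are required")
    if np.ptp(x) == 0:
        # degenerate covariate: MLE is the prevalence-only model
        prev = ncase / len(y)
        return LogisticFit(float(np.log(prev / (1 - prev))), 0.0, True, 0)
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation makes IRLS grumble; fine
        res = model.fit(maxiter=MAX_ITER, tol=1e-10)
    n_iter = len(res.fit_history["deviance"]) - 1
    converged = bool(res.converged) and n_iter < MAX_ITER
    if not converged:
        logger.warning(
            "logistic fit not converged after %d iterations "
            "(likely complete separation); probabilities remain usable",
            n_iter,
        )
    return LogisticFit(float(res.params[0]), float(res.params[1]), converged, n_iter)


def confusion_from_fit(
    fit: LogisticFit, expression, labels, threshold: float = 0.5,
    study_id: str = "",
) -> ConfusionTable:
    """Classify each sample ("case" iff fitted probability >= threshold).

    Ties at exactly the threshold are classified as "case".
    """
    y = _encode_labels(labels).astype(bool)
    pred = fit.predict_proba(expression) >= threshold
    return ConfusionTable(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
        study_id=study_id,
    )


def confusion_table(
    expression, labels, threshold: float = 0.5, study_id: str = ""
) -> ConfusionTable:
    """Fit + classify in one step (the per-study, per-gene unit of work)."""
    fit = fit_logistic(expression, labels)
    return confusion_from_fit(fit, expression, labels, threshold, study_id)


def write_tables(tables, path) -> None:
    """Emit confusion tables as CSV with columns study_id, TP, FP, FN, TN."""
    df = pd.DataFrame(
        [(t.study_id, t.tp, t.fp, t.fn, t.tn) for t in tables],
        columns=["study_id", "TP", "FP", "FN", "TN"],
    )
    df.to_csv(path, index=False)


def read_tables(path) -> list[ConfusionTable]:
    """Read confusion tables from a study_id,TP,FP,FN,TN CSV."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    required = ["study_id", "tp", "fp", "fn", "tn"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"2x2 CSV lacks column(s): {', '.join(missing)}")
    return [
        ConfusionTable(
            tp=int(row[cols["tp"]]), fp=int(row[cols["fp"]]),
            fn=int(row[cols["fn"]]), tn=int(row[cols["tn"]]),
            study_id=str(row[cols["study_id"]]),
        )
        for _, row in df.iterrows()
    ]
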