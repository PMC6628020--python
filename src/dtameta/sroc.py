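"""Moses-Littenberg summary ROC curve.

Each study contributes a point in ROC space; the Moses-Littenberg model
regresses the log diagnostic odds ratio D = logit(TPR) - logit(FPR) on the
threshold proxy S = logit(TPR) + logit(FPR):

    D = a + b * S

(least squares, optionally weighted by the inverse variance of ln DOR).
Inverting the transform gives the summary curve

    TPR(FPR) = expit( a/(1-b) + logit(FPR) * (1+b)/(1-b) ),

which is a proper monotone ROC curve only for |b| < 1.  When the fitted
slope falls outside that range the model is flagged degenerate and the
curve, AUC and Q* are evaluated on the symmetric curve (slope 0, constant
DOR = e^a) with the fitted intercept — the behaviour of classical DTA
meta-analysis software, which reports the symmetric-model summary in that
case.  Q* = expit(a/2) is the point where sensitivity equals specificity
(S = 0 there, so D = a) and depends on the intercept alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = ["SROCModel", "fit_moses", "sroc_curve", "auc", "q_star"]

logger = logging.getLogger(__name__)

#: logit values are clamped to +/- this bound if a raw 0/1 proportion ever
#: reaches the regression (continuity correction upstream should prevent it)
LOGIT_CLAMP = 36.0


@dataclass(frozen=True)
class SROCModel:
    """Fitted Moses-Littenberg regression D = a + b*S."""

    a: float
    b: float
    se_a: float
    se_b: float
    weighted: bool
    n_studies: int

    @property
    def degenerate(self) -> bool:
        """True when |b| >= 1: the asymmetric curve is not monotone and the
        symmetric (slope-0) curve is used for TPR/AUC instead."""
        return abs(self.b) >= 1.0

    @property
    def effective_b(self) -> float:
        return 0.0 if self.degenerate else self.b

    @property
    def auc(self) -> float:
        return auc(self)

    @property
    def q_star(self) -> float:
        return q_star(self)


def _clamped_logit(p: np.ndarray) -> np.ndarray:
    out = np.empty_like(p, dtype=float)
    interior = (p > 0) & (p < 1)
    out[interior] = logit(p[interior])
    if not interior.all():
        logger.warning("logit of exact 0/1 clamped to +/-%g", LOGIT_CLAMP)
        out[p <= 0] = -LOGIT_CLAMP
        out[p >= 1] = LOGIT_CLAMP
    return out


def fit_moses(studies, weighted: bool = False) -> SROCModel:
    """Weighted least-squares fit of D on S over >= 3 studies.

    ``weighted=True`` uses inverse-variance weights 1/var(ln DOR); the
    default is the unweighted fit.  Sensitivities/specificities come from
    the (continuity-corrected where needed) per-study indices.
    """
    studies = list(studies)
    if len(studies) < 3:
        raise ValueError(f"need >= 3 studies to fit an SROC, got {len(studies)}")
    sens = np.array([s.sens for s in studies])
    fpr = np.array([1.0 - s.spec for s in studies])
    lt, lf = _clamped_logit(sens), _clamped_logit(fpr)
    d = lt - lf  # = ln DOR
    s_prox = lt + lf
    if np.ptp(s_prox) == 0:
        raise ValueError(
            "all studies share the same S = logit(sens) + logit(1-spec); "
            "the Moses slope is undefined"
        )
    w = 1.0 / np.array([s.var_ln_dor for s in studies]) if weighted else np.ones(len(d))
    wsum = w.sum()
    s_bar, d_bar = np.sum(w * s_prox) / wsum, np.sum(w * d) / wsum
    sxx = np.sum(w * (s_prox - s_bar) ** 2)
    b = float(np.sum(w * (s_prox - s_bar) * (d - d_bar)) / sxx)
    a = float(d_bar - b * s_bar)
    resid = d - (a + b * s_prox)
    dof = len(d) - 2
    # weighted residual variance; se on the weighted-LS scale
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    se_b = float(np.sqrt(sigma2 / sxx))
    se_a = float(np.sqrt(sigma2 * (1.0 / wsum + s_bar**2 / sxx)))
    model = SROCModel(a=a, b=b, se_a=se_a, se_b=se_b,
                      weighted=weighted, n_studies=len(d))
    if model.degenerate:
        logger.warning(
            "Moses slope b=%.3f outside (-1, 1): asymmetric curve improper; "
            "symmetric (slope-0) curve will be used for TPR/AUC", b,
        )
    return model


def sroc_curve(model: SROCModel, fpr) -> np.ndarray:
    """TPR of the summary curve at one or more FPR values in (0, 1)."""
    fpr_arr = np.asarray(fpr, dtype=float)
    if np.any(fpr_arr <= 0) or np.any(fpr_arr >= 1):
        raise ValueError("fpr must lie strictly inside (0, 1)")
    b = model.effective_b
    tpr = expit(model.a / (1 - b) + logit(fpr_arr) * (1 + b) / (1 - b))
    return tpr if np.ndim(fpr) else float(tpr)


def auc(model: SROCModel, step: float = 1e-4, fpr_range: tuple | None = None) -> float:
    """Trapezoidal AUC of the summary curve over FPR in (0, 1).

    The open endpoints are handled by their limits (TPR -> 0 and 1 for
    |b| < 1).  ``fpr_range=(lo, hi)`` restricts integration to the observed
    FPR range instead of extrapolating over the full axis; the result is
    then the unnormalized area of that segment plus nothing else.
    """
    if fpr_range is None:
        lo, hi, endpoints = 0.0, 1.0, True
    else:
        lo, hi = fpr_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("fpr_range must satisfy 0 <= lo < hi <= 1")
        endpoints = False
    n = max(3, int(round((hi - lo) / step)) + 1)
    grid = np.linspace(lo, hi, n)
    inner = grid[(grid > 0) & (grid < 1)]
    tpr = sroc_curve(model, inner)
    xs, ys = inner, tpr
    if endpoints or lo == 0.0:
        xs = np.concatenate([[0.0], xs])
        ys = np.concatenate([[0.0], ys])
    if endpoints or hi == 1.0:
        xs = np.concatenate([xs, [1.0]])
        ys = np.concatenate([ys, [1.0]])
    return float(np.trapezoid(ys, xs))


def q_star(model: SROCModel) -> float:
    """The sensitivity = specificity point of the curve: expit(a/2).

    At that point S = 0, so D = a regardless of the slope.
    """
    return float(expit(model.a / 2.0))
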