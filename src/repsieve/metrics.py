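"""Prediction-performance measures for fitted risk scores.

A fitted model is summarized by its risk score r_i = beta' Z_i over the
selected features (no intercept: both measures below are invariant to
location shifts).  Binary outcomes are scored by ROC AUC; survival
outcomes by Harrell's concordance C-index (higher risk <-> shorter
survival) and by the -log10 p-value of a univariate Cox regression of
the outcome on the risk score.  Ties in scores count 1/2 in both AUC and
C, so constant scores give exactly 0.5.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .regression import FitResult, fit_cox, wald_neglog10p

__all__ = ["risk_score", "roc_auc", "roc_points", "harrell_c",
           "riskscore_neglog10p"]


def risk_score(fit: FitResult, X_sub: np.ndarray) -> np.ndarray:
    """Linear predictor beta' Z over the fit's features (intercept excluded).

    ``X_sub`` columns must align with ``fit.feature_ids``.
    """
    X_sub = np.atleast_2d(np.asarray(X_sub, dtype=float))
    if X_sub.shape[1] != len(fit.feature_ids):
        raise ValueError(
            f"X_sub has {X_sub.shape[1]} columns but the fit covers "
            f"{len(fit.feature_ids)} features"
        )
    r = X_sub @ fit.coef if len(fit.feature_ids) else np.zeros(X_sub.shape[0])
    if not np.isfinite(r).all():
        raise ValueError("non-finite risk scores")
    return r


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC = P(r_case > r_control) + 0.5 P(tie) (Mann-Whitney form)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ROC curve as an (FPR, TPR) two-column array, for plotting/export."""
    fpr, tpr, _ = roc_curve(np.asarray(y), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def harrell_c(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index, oriented so higher risk means shorter
    survival.

    A pair is usable iff the shorter observed time belongs to a subject
    with an event; concordant when that subject has the higher score;
    score ties count 1/2.  Tied observed times with both events count as
    usable pairs contributing 1/2; a tied event/censored pair is
    unusable.  (This is the classical definition; some libraries score
    tied times differently, which only matters when times can tie.)
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(scores)
    if not (len(time) == len(event) == n):
        raise ValueError("scores, time, event must have equal length")
    # vectorized over all ordered pairs (i earlier than j)
    earlier = (time[:, None] < time[None, :]) & event[:, None]
    num = (
        np.sum(earlier & (scores[:, None] > scores[None, :]))
        + 0.5 * np.sum(earlier & (scores[:, None] == scores[None, :]))
    )
    den = float(np.sum(earlier))
    tied = (time[:, None] == time[None, :]) & event[:, None] & event[None, :]
    n_tied_pairs = (np.sum(tied) - int(event.sum())) / 2.0   # off-diagonal
    num += 0.5 * n_tied_pairs
    den += n_tied_pairs
    if den == 0:
        raise ValueError("no usable pairs in the data")
    return float(num / den)


def riskscore_neglog10p(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """-log10 p of the univariate Cox regression of (time, event) on r.

    Computed from the Wald z on the log scale, so extremely small
    p-values (common for strong scores) do not underflow.
    """
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("risk scores are constant; the univariate fit is undefined")
    fit = fit_cox(scores[:, None], time, event, ["risk_score"])
    if not fit.converged:
        raise ValueError("univariate Cox fit on the risk score did not converge")
    return float(wald_neglog10p(float(fit.coef[0]), float(fit.se[0])))
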