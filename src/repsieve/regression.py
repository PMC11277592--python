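"""Unpenalized maximum-likelihood fitting of logistic and Cox models.

Newton-Raphson fitting of low-dimensional logistic regressions and Cox
proportional-hazards regressions (Efron tie handling), exposing per-
coefficient Wald significance.  These fits are the inner loop of the
significance-threshold stepwise search: a single block sieve issues
thousands of small fits, so both families are implemented as *batched*
Newton iterations over stacked design matrices -- one linear-algebra call
serves every candidate of an insertion scan simultaneously.

Conventions
-----------
* Logistic fits always carry an intercept; the intercept is reported
  separately from the covariate coefficients and is never tested.
* Cox fits have no intercept (absorbed into the baseline hazard).
* Significance is the two-sided Wald test z = beta / se against N(0,1),
  computed from the observed-information covariance at the optimum.
* Convergence: relative log-likelihood change below ``LOGLIK_RTOL``
  within ``MAX_NEWTON_ITER`` iterations, with step halving.  Fits that
  fail (separation, monotone likelihood, singular information) are
  returned with ``converged=False``, never silently as valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import qr as _qr
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "FitResult",
    "CollinearityError",
    "fit_logistic",
    "fit_cox",
    "cox_loglik",
    "wald_neglog10p",
]

log = logging.getLogger(__name__)

#: relative log-likelihood tolerance declaring Newton convergence
LOGLIK_RTOL = 1e-8
#: maximum Newton iterations before a fit is declared non-convergent
MAX_NEWTON_ITER = 100
#: max |fitted prob - y| below which a logistic fit is perfectly separated
_SEPARATION_TOL = 1e-6
#: linear-predictor spread beyond which a Cox fit is treated as divergent
_ETA_SPREAD_MAX = 250.0


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, offending: Sequence[str]):
        self.offending = list(offending)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(map(str, self.offending))
        )


@dataclass
class FitResult:
    """One converged (or flagged) regression fit on a covariate subset.

    ``coef``/``se``/``p_values`` are aligned with ``feature_ids``; the
    logistic intercept is kept apart so downstream risk scores
    (``beta' Z``, no intercept) and selection logic never touch it.
    """

    family: str                       # "logistic" | "cox"
    feature_ids: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    loglik: float
    converged: bool
    intercept: float | None = None
    intercept_se: float | None = None
    n_obs: int = 0
    n_iter: int = 0

    def __post_init__(self) -> None:
        k = len(self.feature_ids)
        if not (len(self.coef) == len(self.se) == len(self.p_values) == k):
            raise ValueError("coef / se / p_values length mismatch with feature_ids")
        if self.converged and not np.isfinite(self.loglik):
            raise ValueError("converged fit must have finite log-likelihood")


# ---------------------------------------------------------------------------
# shared numerics
# ---------------------------------------------------------------------------

def _check_full_rank(M: np.ndarray, names: Sequence[str]) -> None:
    """Raise CollinearityError naming columns beyond the numerical rank."""
    if M.shape[1] == 0:
        return
    _, R, piv = _qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = (diag.max() if diag.size else 0.0) * max(M.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < M.shape[1]:
        raise CollinearityError([names[j] for j in piv[rank:]])


def _solve_info_batch(H: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve H x = g for a stack of information matrices.

    Returns (x, bad) where ``bad`` flags items whose information matrix is
    (near-)singular -- those steps are zeroed and the fit is abandoned.
    """
    C, d, _ = H.shape
    bad = np.zeros(C, dtype=bool)
    # cheap conditioning probe through the Cholesky diagonal
    try:
        L = np.linalg.cholesky(H)
        dg = np.einsum("cii->ci", L)
        bad |= dg.min(axis=1) <= dg.max(axis=1) * 1e-8
    except np.linalg.LinAlgError:
        for c in range(C):
            try:
                Lc = np.linalg.cholesky(H[c])
                if np.diag(Lc).min() <= np.diag(Lc).max() * 1e-8:
                    bad[c] = True
            except np.linalg.LinAlgError:
                bad[c] = True
    x = np.zeros_like(g)
    ok = ~bad
    if ok.any():
        x[ok] = np.linalg.solve(H[ok], g[ok][..., None])[..., 0]
    nonfin = ~np.isfinite(x).all(axis=1)
    if nonfin.any():
        x[nonfin] = 0.0
        bad |= nonfin
    return x, bad


def _cov_batch(H: np.ndarray, bad: np.ndarray) -> np.ndarray:
    cov = np.full_like(H, np.nan)
    ok = ~bad
    if ok.any():
        cov[ok] = np.linalg.inv(H[ok])
    return cov


def _wald_p(coef: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Two-sided Wald p-values; non-positive variances give p = 1."""
    from scipy.special import erfc

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, coef / np.sqrt(var), 0.0)
    return erfc(np.abs(z) / np.sqrt(2.0))  # == 2 * norm.sf(|z|)


def wald_neglog10p(coef: float, se: float) -> float:
    """-log10 of the two-sided Wald p-value, stable for extreme z."""
    if not (se > 0 and np.isfinite(coef)):
        raise ValueError("need finite coefficient and positive standard error")
    z = abs(coef) / se
    return -(np.log(2.0) + norm.logsf(z)) / np.log(10.0)


# ---------------------------------------------------------------------------
# logistic family
# ---------------------------------------------------------------------------

def _eta_ll(A: np.ndarray, y: np.ndarray, theta: np.ndarray):
    eta = (A @ theta[..., None])[..., 0]
    return eta, eta @ y - np.logaddexp(0.0, eta).sum(axis=1)


def _logit_ll(A: np.ndarray, y: np.ndarray, theta: np.ndarray) -> np.ndarray:
    return _eta_ll(A, y, theta)[1]


def _logit_newton(
    A: np.ndarray, y: np.ndarray, init: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Batched Newton MLE for C logistic models sharing the response.

    Parameters
    ----------
    A : (C, n, d) stacked design matrices, intercept column included.
    y : (n,) binary response shared by every item in the batch.
    init : optional (C, d) starting values (warm start from a parent fit).

    Returns
    -------
    theta, cov, loglik, converged, n_iter

    The batch shrinks as individual candidates converge, so one slow
    candidate does not cost full passes over the whole scan.
    """
    C, n, d = A.shape
    y = np.asarray(y, dtype=float)
    theta_full = np.zeros((C, d)) if init is None else np.array(init, dtype=float)
    ll_full = np.empty(C)
    conv_full = np.zeros(C, dtype=bool)
    dead_full = np.zeros(C, dtype=bool)
    idx = np.arange(C)
    Aa, theta = A, theta_full.copy()
    eta, ll = _eta_ll(Aa, y, theta)
    it = 0
    while idx.size and it < MAX_NEWTON_ITER:
        it += 1
        p = expit(eta)
        At = Aa.transpose(0, 2, 1)
        g = (At @ (y[None, :] - p)[..., None])[..., 0]
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = At @ (Aa * w[..., None])
        step, bad = _solve_info_batch(H, g)
        cand = theta + step
        eta_new, ll_new = _eta_ll(Aa, y, cand)
        for _ in range(30):                 # step halving
            worse = (ll_new < ll - 1e-10) & ~bad
            if not worse.any():
                break
            step[worse] *= 0.5
            cand[worse] = theta[worse] + step[worse]
            eta_new[worse], ll_new[worse] = _eta_ll(Aa[worse], y, cand[worse])
        ok = ~bad
        done = ok & (np.abs(ll_new - ll) <= LOGLIK_RTOL * (np.abs(ll) + LOGLIK_RTOL))
        theta = np.where(ok[:, None], cand, theta)
        eta = np.where(ok[:, None], eta_new, eta)
        ll = np.where(ok, ll_new, ll)
        finished = bad | done
        if finished.any():
            gidx = idx[finished]
            theta_full[gidx] = theta[finished]
            ll_full[gidx] = ll[finished]
            conv_full[gidx] = done[finished]
            dead_full[gidx] = bad[finished]
            keep = ~finished
            idx = idx[keep]
            Aa = Aa[keep]
            theta = theta[keep]
            eta = eta[keep]
            ll = ll[keep]
    if idx.size:                            # hit the iteration cap
        theta_full[idx] = theta
        ll_full[idx] = ll
    # perfect separation: fitted probabilities equal the response
    eta_f = (A @ theta_full[..., None])[..., 0]
    pfin = expit(eta_f)
    sep = np.max(np.abs(pfin - y[None, :]), axis=1) < _SEPARATION_TOL
    if sep.any():
        log.debug("logistic fit separated for %d of %d candidates", sep.sum(), C)
    conv_full &= ~sep
    w = np.clip(pfin * (1.0 - pfin), 1e-12, None)
    H = A.transpose(0, 2, 1) @ (A * w[..., None])
    cov = _cov_batch(H, dead_full | sep)
    return theta_full, cov, ll_full, conv_full & ~dead_full, it


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str] | None = None,
) -> FitResult:
    """Maximum-likelihood logistic regression of y on X plus an intercept.

    ``X`` may have zero columns (intercept-only model).  Rank-deficient
    designs raise :class:`CollinearityError` naming the offending columns;
    separated or otherwise non-convergent fits come back flagged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    y = np.asarray(y)
    n, k = X.shape
    if n != len(y):
        raise ValueError("X and y disagree on the number of subjects")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be coded 0/1")
    if k >= n:
        raise ValueError(f"need fewer covariates than subjects (k={k}, n={n})")
    ids = tuple(feature_ids) if feature_ids is not None else tuple(
        f"x{j}" for j in range(k)
    )
    if len(ids) != k:
        raise ValueError("feature_ids length mismatch")
    A1 = np.column_stack([np.ones(n), X])
    _check_full_rank(A1, ("(intercept)",) + ids)
    theta, cov, ll, conv, it = _logit_newton(A1[None, :, :], np.asarray(y, float))
    th, cv = theta[0], cov[0]
    var = np.diag(cv) if np.isfinite(cv).all() else np.full(k + 1, np.nan)
    pvals = _wald_p(th[1:], var[1:]) if conv[0] else np.ones(k)
    return FitResult(
        family="logistic",
        feature_ids=ids,
        coef=th[1:].copy(),
        se=np.sqrt(np.where(var[1:] > 0, var[1:], np.nan)),
        p_values=pvals,
        loglik=float(ll[0]),
        converged=bool(conv[0]),
        intercept=float(th[0]),
        intercept_se=float(np.sqrt(var[0])) if var[0] > 0 else None,
        n_obs=n,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Cox family (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class _CoxStructure:
    """Sort order and tie-group bookkeeping for one (time, event) outcome."""

    order: np.ndarray        # ascending-time permutation of subjects
    grp_start: np.ndarray    # (G,) first sorted index of each distinct event time
    event_pos: np.ndarray    # (E,) sorted indices of events, grouped by time
    event_bounds: np.ndarray # (G,) reduceat offsets into event_pos
    counts: np.ndarray       # (G,) number of events per distinct event time
    max_mult: int            # largest tie multiplicity
    n: int


def _cox_structure(time: np.ndarray, event: np.ndarray) -> _CoxStructure:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    ts = time[order]
    ds = event[order]
    ev_times = np.unique(ts[ds])
    grp_start = np.searchsorted(ts, ev_times, side="left")
    event_pos = np.nonzero(ds)[0]
    grp_of_event = np.searchsorted(ev_times, ts[event_pos])
    counts = np.bincount(grp_of_event, minlength=len(ev_times))
    event_bounds = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.intp)
    return _CoxStructure(
        order=order,
        grp_start=grp_start.astype(np.intp),
        event_pos=event_pos,
        event_bounds=event_bounds,
        counts=counts.astype(float),
        max_mult=int(counts.max()) if counts.size else 0,
        n=len(time),
    )


def _suffix_groups(arr: np.ndarray, grp_start: np.ndarray) -> np.ndarray:
    """Risk-set (suffix) sums of ``arr`` over axis 1 at each tie-group start."""
    csum = np.cumsum(arr[:, ::-1], axis=1)[:, ::-1]
    return csum[:, grp_start]


def _event_group_sums(arr_e: np.ndarray, st: "_CoxStructure") -> np.ndarray:
    """Sums of event rows within each tie group (identity when no ties)."""
    if st.max_mult == 1:
        return arr_e
    return np.add.reduceat(arr_e, st.event_bounds, axis=1)


def _cox_ll_grad_hess(
    A: np.ndarray, theta: np.ndarray, st: _CoxStructure, want_derivs: bool = True
):
    """Efron partial log-likelihood (+ gradient, observed information).

    ``A`` is (C, n, d), *already sorted by ascending time*.
    """
    C, n, d = A.shape
    eta = (A @ theta[..., None])[..., 0]
    shift = eta.max(axis=1, keepdims=True)
    r = np.exp(eta - shift)
    ll = eta[:, st.event_pos].sum(axis=1)
    # per-event log(phi) carries the shift back in
    if want_derivs:
        # one fused suffix-cumsum over [r, r*x, r*x*x'] instead of three
        W = np.empty((C, n, 1 + d + d * d))
        W[:, :, 0] = r
        rx = r[:, :, None] * A                                  # (C, n, d)
        W[:, :, 1 : 1 + d] = rx
        rxx = rx[:, :, :, None] * A[:, :, None, :]              # (C, n, d, d)
        W[:, :, 1 + d :] = rxx.reshape(C, n, d * d)
        SW = _suffix_groups(W, st.grp_start)
        S0 = SW[:, :, 0]
        S1 = SW[:, :, 1 : 1 + d]
        S2 = SW[:, :, 1 + d :].reshape(C, -1, d, d)
        if st.max_mult > 1:
            s0 = _event_group_sums(r[:, st.event_pos], st)
            s1 = _event_group_sums(rx[:, st.event_pos], st)
            s2 = _event_group_sums(rxx[:, st.event_pos], st)
        g = A[:, st.event_pos].sum(axis=1)                      # (C, d)
        I = np.zeros((C, d, d))
    else:
        S0 = _suffix_groups(r, st.grp_start)                    # (C, G)
        if st.max_mult > 1:
            s0 = _event_group_sums(r[:, st.event_pos], st)
        g = I = None
    if st.max_mult == 1:                     # no tied event times (common)
        ll -= (np.log(S0) + shift).sum(axis=1)
        if want_derivs:
            u = S1 / S0[..., None]                              # (C, G, d)
            g -= u.sum(axis=1)
            I += (S2 / S0[..., None, None]).sum(axis=1)
            I -= u.transpose(0, 2, 1) @ u
        return ll, g, I
    dj = st.counts                                              # (G,)
    for l in range(st.max_mult):
        msk = dj > l
        f = (l / dj[msk])
        phi = S0[:, msk] - f * s0[:, msk]                       # (C, Gm)
        ll -= (np.log(phi) + shift).sum(axis=1)
        if want_derivs:
            psi = S1[:, msk] - f[None, :, None] * s1[:, msk]
            Psi = S2[:, msk] - f[None, :, None, None] * s2[:, msk]
            u = psi / phi[..., None]                            # (C, Gm, d)
            g -= u.sum(axis=1)
            I += (Psi / phi[..., None, None]).sum(axis=1)
            I -= u.transpose(0, 2, 1) @ u
    return ll, g, I


def _cox_ll(A: np.ndarray, theta: np.ndarray, st: _CoxStructure) -> np.ndarray:
    return _cox_ll_grad_hess(A, theta, st, want_derivs=False)[0]


def _cox_newton(
    A: np.ndarray, st: _CoxStructure, init: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Batched Newton maximization of the Efron partial log-likelihood.

    Same active-set scheme as the logistic solver: converged or abandoned
    candidates drop out of subsequent passes.
    """
    C, n, d = A.shape
    theta_full = np.zeros((C, d)) if init is None else np.array(init, dtype=float)
    ll_full = np.empty(C)
    conv_full = np.zeros(C, dtype=bool)
    dead_full = np.zeros(C, dtype=bool)
    idx = np.arange(C)
    Aa, theta = A, theta_full.copy()
    ll = np.full(C, -np.inf)
    it = 0
    while idx.size and it < MAX_NEWTON_ITER:
        it += 1
        ll, g, I = _cox_ll_grad_hess(Aa, theta, st)
        step, bad = _solve_info_batch(I, g)
        cand = theta + step
        ll_new = _cox_ll(Aa, cand, st)
        for _ in range(30):
            worse = (ll_new < ll - 1e-10) & ~bad
            if not worse.any():
                break
            step[worse] *= 0.5
            cand[worse] = theta[worse] + step[worse]
            ll_new[worse] = _cox_ll(Aa[worse], cand[worse], st)
        ok = ~bad
        done = ok & (np.abs(ll_new - ll) <= LOGLIK_RTOL * (np.abs(ll) + LOGLIK_RTOL))
        theta = np.where(ok[:, None], cand, theta)
        ll = np.where(ok, ll_new, ll)
        finished = bad | done
        if finished.any():
            gidx = idx[finished]
            theta_full[gidx] = theta[finished]
            ll_full[gidx] = ll[finished]
            conv_full[gidx] = done[finished]
            dead_full[gidx] = bad[finished]
            keep = ~finished
            idx = idx[keep]
            Aa = Aa[keep]
            theta = theta[keep]
            ll = ll[keep]
    if idx.size:
        theta_full[idx] = theta
        ll_full[idx] = ll
    # monotone-likelihood escape: linear predictor spread blowing up
    eta = (A @ theta_full[..., None])[..., 0]
    spread = eta.max(axis=1) - eta.min(axis=1) if n else np.zeros(C)
    runaway = spread > _ETA_SPREAD_MAX
    if runaway.any():
        log.debug("cox fit diverged for %d of %d candidates", runaway.sum(), C)
    conv_full &= ~runaway
    _, _, I = _cox_ll_grad_hess(A, theta_full, st)
    cov = _cov_batch(I, dead_full | runaway)
    return theta_full, cov, ll_full, conv_full & ~dead_full, it


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    feature_ids: Sequence[str] | None = None,
) -> FitResult:
    """Cox proportional-hazards MLE by partial-likelihood maximization.

    Ties are handled with Efron's approximation.  The model has no
    intercept; ``X`` must have at least one column and the outcome at
    least one event.  A covariate carrying no information (constant, or a
    linear combination of the others) raises :class:`CollinearityError`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if len(time) != n or len(event) != n:
        raise ValueError("X, time, event disagree on the number of subjects")
    if k < 1:
        raise ValueError("the Cox model needs at least one covariate")
    if k >= n:
        raise ValueError(f"need fewer covariates than subjects (k={k}, n={n})")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be coded 0/1")
    if not np.asarray(event, bool).any():
        raise ValueError("no events observed; the partial likelihood is empty")
    ids = tuple(feature_ids) if feature_ids is not None else tuple(
        f"x{j}" for j in range(k)
    )
    if len(ids) != k:
        raise ValueError("feature_ids length mismatch")
    # the partial likelihood is location-invariant: rank-check centred X
    _check_full_rank(X - X.mean(axis=0), ids)
    st = _cox_structure(time, event)
    A = X[st.order][None, :, :]
    theta, cov, ll, conv, it = _cox_newton(A, st)
    th, cv = theta[0], cov[0]
    var = np.diag(cv) if np.isfinite(cv).all() else np.full(k, np.nan)
    pvals = _wald_p(th, var) if conv[0] else np.ones(k)
    return FitResult(
        family="cox",
        feature_ids=ids,
        coef=th.copy(),
        se=np.sqrt(np.where(var > 0, var, np.nan)),
        p_values=pvals,
        loglik=float(ll[0]),
        converged=bool(conv[0]),
        n_obs=n,
        n_iter=it,
    )


def cox_loglik(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> float:
    """Efron partial log-likelihood at a fixed coefficient vector.

    Used for cross-validated deviance of penalized comparators and as a
    numerical check; ``beta`` may be all zeros (null model).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    st = _cox_structure(time, event)
    A = X[st.order][None, :, :]
    return float(_cox_ll(A, beta[None, :], st)[0])
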