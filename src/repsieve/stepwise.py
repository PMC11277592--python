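"""Forward stepwise variable selection driven by significance thresholds.

The search starts from an intercept-only model (logistic) or an empty
model (Cox).  Each step fits, for every remaining candidate, the current
model augmented by that candidate, and inserts the candidate whose own
Wald p-value in the augmented joint model is smallest -- provided it is
below the insertion threshold alpha_in.  After each insertion a deletion
sweep removes, one at a time with refitting, any previously included
covariate whose joint-model p-value exceeds the deletion threshold
alpha_out (>= alpha_in).  The procedure stops when no candidate
qualifies, guaranteeing on exit that every retained coefficient is
significant at alpha_out.

The insertion scan is the hot path: all augmented models of one scan are
fitted in a single batched Newton call (see :mod:`repsieve.regression`),
warm-started from the current joint fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import Dataset
from .regression import (
    FitResult,
    _cox_newton,
    _cox_structure,
    _logit_newton,
    _wald_p,
    fit_cox,
    fit_logistic,
)

__all__ = ["StepwiseConfig", "SelectionResult", "forward_stepwise", "joint_refit"]

log = logging.getLogger(__name__)


@dataclass
class StepwiseConfig:
    """Thresholds and safety caps for one stepwise search.

    ``alpha_in`` gates insertion (candidate joint-model p must fall
    strictly below it); ``alpha_out >= alpha_in`` gates deletion.
    ``max_selected`` is a hard cap guarding against pathological runs.
    """

    alpha_in: float
    alpha_out: float
    family: str = "logistic"
    max_selected: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_in < 1.0):
            raise ValueError("alpha_in must lie in [0, 1)")
        if not (0.0 < self.alpha_out < 1.0) and self.alpha_out != 0.0:
            raise ValueError("alpha_out must lie in [0, 1)")
        if self.alpha_out < self.alpha_in:
            raise ValueError("alpha_out (deletion) must be >= alpha_in (insertion)")
        if self.family not in ("logistic", "cox"):
            raise ValueError("family must be 'logistic' or 'cox'")
        if self.max_selected < 1:
            raise ValueError("max_selected must be positive")


@dataclass
class SelectionResult:
    """Ordered selection, its final joint fit, and the step-by-step trace."""

    selected: list[str]
    fit: FitResult | None
    trace: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


# ---------------------------------------------------------------------------
# family engines: shared data prep + batched scans
# ---------------------------------------------------------------------------

class _LogisticEngine:
    family = "logistic"

    def __init__(self, ds: Dataset):
        self.ds = ds
        self.X = ds.X
        self.y = np.asarray(ds.y, dtype=float)
        self.n = ds.n
        self._uni_p: np.ndarray | None = None
        pbar = self.y.mean()
        if 0.0 < pbar < 1.0:
            self.null_theta = np.array([np.log(pbar / (1.0 - pbar))])
            self.null_ll = float(
                self.n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
            )
        else:  # degenerate single-class response
            self.null_theta = np.array([0.0])
            self.null_ll = -np.inf

    def scan(self, sel: list[int], cand: np.ndarray, warm: np.ndarray | None):
        C = len(cand)
        d = len(sel) + 2
        A = np.empty((C, self.n, d))
        A[:, :, 0] = 1.0
        if sel:
            A[:, :, 1:-1] = self.X[:, sel][None, :, :]
        A[:, :, -1] = self.X[:, cand].T
        init = None
        if warm is not None:
            init = np.zeros((C, d))
            init[:, :-1] = warm[None, :]
        theta, cov, ll, conv, _ = _logit_newton(A, self.y, init)
        p = np.where(conv, _wald_p(theta[:, -1], cov[:, -1, -1]), 1.0)
        return p, conv

    def fit(self, sel: list[int]) -> FitResult:
        if not sel:
            return FitResult(
                family="logistic",
                feature_ids=(),
                coef=np.empty(0),
                se=np.empty(0),
                p_values=np.empty(0),
                loglik=self.null_ll,
                converged=np.isfinite(self.null_ll),
                intercept=float(self.null_theta[0]),
                n_obs=self.n,
            )
        return fit_logistic(
            self.X[:, sel], self.ds.y, [self.ds.feature_ids[j] for j in sel]
        )

    def warm_theta(self, fit: FitResult) -> np.ndarray:
        return np.concatenate([[fit.intercept], fit.coef])

    def univariate_p(self, cand: np.ndarray) -> np.ndarray:
        """First-scan p-values: identical for every block containing the
        feature, so computed once per dataset (lazily, in chunks) and
        cached across permutations."""
        return _cached_univariate(self, cand, self.null_theta)


class _CoxEngine:
    family = "cox"

    def __init__(self, ds: Dataset):
        self.ds = ds
        self.st = _cox_structure(ds.time, ds.event)
        self.Xs = ds.X[self.st.order]         # time-sorted once, reused per block
        self.n = ds.n
        self._uni_p: np.ndarray | None = None

    def scan(self, sel: list[int], cand: np.ndarray, warm: np.ndarray | None):
        C = len(cand)
        d = len(sel) + 1
        A = np.empty((C, self.n, d))
        if sel:
            A[:, :, :-1] = self.Xs[:, sel][None, :, :]
        A[:, :, -1] = self.Xs[:, cand].T
        init = None
        if warm is not None:
            init = np.zeros((C, d))
            init[:, :-1] = warm[None, :]
        theta, cov, ll, conv, _ = _cox_newton(A, self.st, init)
        p = np.where(conv, _wald_p(theta[:, -1], cov[:, -1, -1]), 1.0)
        return p, conv

    def fit(self, sel: list[int]) -> FitResult:
        if not sel:
            from .regression import _cox_ll

            ll = float(
                _cox_ll(np.zeros((1, self.n, 0)), np.zeros((1, 0)), self.st)[0]
            )
            return FitResult(
                family="cox",
                feature_ids=(),
                coef=np.empty(0),
                se=np.empty(0),
                p_values=np.empty(0),
                loglik=ll,
                converged=True,
                n_obs=self.n,
            )
        return fit_cox(
            self.ds.X[:, sel],
            self.ds.time,
            self.ds.event,
            [self.ds.feature_ids[j] for j in sel],
        )

    def warm_theta(self, fit: FitResult) -> np.ndarray:
        return fit.coef

    def univariate_p(self, cand: np.ndarray) -> np.ndarray:
        """See _LogisticEngine.univariate_p."""
        return _cached_univariate(self, cand, None)


def _cached_univariate(engine, cand: np.ndarray, warm) -> np.ndarray:
    if engine._uni_p is None:
        engine._uni_p = np.full(engine.ds.m, np.nan)
    need = cand[np.isnan(engine._uni_p[cand])]
    for lo in range(0, len(need), 512):
        chunk = need[lo : lo + 512]
        engine._uni_p[chunk], _ = engine.scan([], chunk, warm)
    return engine._uni_p[cand]


def _make_engine(ds: Dataset):
    return _LogisticEngine(ds) if ds.family == "logistic" else _CoxEngine(ds)


# ---------------------------------------------------------------------------
# the search
# ---------------------------------------------------------------------------

def forward_stepwise(
    data: Dataset,
    candidates: Sequence[str],
    config: StepwiseConfig,
    _engine=None,
) -> SelectionResult:
    """Forward stepwise search over ``candidates`` under ``config``.

    Candidates are considered in original feature order; ties in the
    minimal p-value break toward the lowest original feature index, so
    the result is deterministic given the data.  A candidate whose
    augmented fit fails to converge (separation, collinearity with the
    current model) is ineligible at that step.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    if config.family != data.family:
        raise ValueError(
            f"config family {config.family!r} does not match data ({data.family!r})"
        )
    engine = _engine if _engine is not None else _make_engine(data)
    cand_cols = sorted(data.col(f) for f in set(candidates))
    if len(cand_cols) != len(candidates):
        raise ValueError("duplicate ids in candidate list")

    selected: list[int] = []
    trace: list[tuple[str, str, float]] = []
    fit = engine.fit(selected)
    warm = engine.warm_theta(fit)
    visited = {frozenset()}
    deleted_at: set[tuple[frozenset, int]] = set()   # (model state, feature col)
    ever_converged = False

    while len(selected) < config.max_selected:
        state = frozenset(selected)
        remaining = np.array(
            [
                c
                for c in cand_cols
                if c not in state and (state, c) not in deleted_at
            ],
            dtype=np.intp,
        )
        if remaining.size == 0:
            break
        if not selected:
            pvals = engine.univariate_p(remaining)
        else:
            pvals, _ = engine.scan(selected, remaining, warm)
        ever_converged = ever_converged or bool((pvals < 1.0).any())
        best = int(np.argmin(pvals))          # ties -> lowest original index
        if not (pvals[best] < config.alpha_in):
            break
        col = int(remaining[best])
        selected.append(col)
        trace.append(("insert", data.feature_ids[col], float(pvals[best])))
        fit = engine.fit(selected)

        # deletion sweep: one at a time, refitting; the just-inserted
        # covariate is protected while others remain deletable, but is
        # itself removed if deletions push its own p above alpha_out.
        while len(selected) > 0:
            pv = fit.p_values if fit.converged else np.ones(len(selected))
            deletable = [i for i, c in enumerate(selected) if c != col]
            over = [i for i in deletable if pv[i] > config.alpha_out]
            if over:
                i_del = max(over, key=lambda i: pv[i])
            elif col in selected and pv[selected.index(col)] > config.alpha_out:
                i_del = selected.index(col)
            else:
                break
            dropped = selected.pop(i_del)
            deleted_at.add((frozenset(selected), dropped))
            trace.append(("delete", data.feature_ids[dropped], float(pv[i_del])))
            fit = engine.fit(selected)

        warm = engine.warm_theta(fit)
        new_state = frozenset(selected)
        if new_state in visited:
            log.warning("stepwise revisited a model state; stopping")
            break
        visited.add(new_state)

    if not selected and not ever_converged:
        log.warning("no candidate model converged; returning empty selection")
    ids = [data.feature_ids[c] for c in selected]
    return SelectionResult(selected=ids, fit=fit, trace=trace)


def joint_refit(data: Dataset, selected: Sequence[str], family: str) -> FitResult:
    """One unpenalized joint fit on exactly the selected features.

    This is the fit that gets reported and serialized for prediction; by
    construction it reproduces ``SelectionResult.fit`` when ``selected``
    came from :func:`forward_stepwise` on the same data.
    """
    if len(selected) == 0:
        raise ValueError("selected feature list is empty")
    if len(selected) >= data.n:
        raise ValueError("more selected features than subjects")
    X = data.columns(selected)
    if family == "logistic":
        return fit_logistic(X, data.y, list(selected))
    if family == "cox":
        return fit_cox(X, data.time, data.event, list(selected))
    raise ValueError("family must be 'logistic' or 'cox'")
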