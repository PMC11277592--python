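"""Synthetic high-dimensional data with a handful of planted predictors.

The generator emulates a microarray-like study: m standard-Gaussian
features arranged in independent blocks of 20 with within-block
compound-symmetry (equicorrelation) rho, of which m1 features -- placed
pairwise into m1/2 blocks -- truly drive the outcome with
alternating-sign coefficients.  Binary outcomes follow a logistic model
with zero intercept; survival outcomes follow a proportional-hazards
model with constant baseline hazard h0 (exponential event times) and
uniform censoring calibrated to a target censoring proportion: U(0, a)
for the reference 30% level, and U(a, a+b) -- the accrual window a held
at its 30% value plus extra follow-up b -- for lighter censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .data import Dataset

__all__ = [
    "SimConfig",
    "TruthSet",
    "gen_features",
    "place_true_features",
    "gen_binary_outcome",
    "gen_survival_outcome",
    "calibrate_censoring",
    "holdout_split",
    "simulate_dataset",
]

#: censoring level generated from U(0, a); lighter levels reuse its ``a``
REFERENCE_CENSORING = 0.30
#: fixed seed of the calibration sample -- calibration is a property of the
#: data-generating process, not of any single replicate
_CALIBRATION_SEED = 20240719
_CALIBRATION_DRAWS = 400_000
#: calibration accuracy on the censoring fraction
CALIBRATION_TOL = 0.005


@dataclass
class SimConfig:
    """Data-generating-process parameters for one simulated study arm."""

    family: str = "binary"            # "binary" | "survival"
    n: int = 400
    m: int = 10_000
    block_len: int = 20
    rho: float = 0.2
    m1: int = 6
    beta_magnitude: float | None = None   # defaults: 2.0 binary, 0.7 survival
    baseline_hazard: float = 0.1
    censor_target: float | None = 0.30
    censor_a: float | None = None
    censor_b: float | None = None
    seed: int = 0
    randomize_placement: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("binary", "survival"):
            raise ValueError("family must be 'binary' or 'survival'")
        if self.beta_magnitude is None:
            self.beta_magnitude = 2.0 if self.family == "binary" else 0.7
        if self.m % self.block_len != 0:
            raise ValueError("m must be divisible by block_len")
        if self.m1 % 2 != 0:
            raise ValueError("m1 must be even (true features are planted in pairs)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.m1 // 2 > self.m // self.block_len:
            raise ValueError("not enough blocks to hold m1/2 true-feature pairs")
        if self.censor_target is not None and not (0.0 < self.censor_target < 1.0):
            raise ValueError("censor_target must lie in (0, 1) or be None")

    @property
    def n_blocks(self) -> int:
        return self.m // self.block_len

    def feature_ids(self) -> list[str]:
        width = len(str(self.m))
        return [f"f{j + 1:0{width}d}" for j in range(self.m)]


@dataclass
class TruthSet:
    """Identifiers and coefficients of the planted predictors."""

    true_ids: list[str]
    true_betas: np.ndarray
    true_cols: np.ndarray      # column indices into the generated matrix

    def __post_init__(self) -> None:
        if not (len(self.true_ids) == len(self.true_betas) == len(self.true_cols)):
            raise ValueError("truth fields length mismatch")


def _rngs(cfg: SimConfig) -> tuple[np.random.Generator, ...]:
    """Independent streams for features / placement / outcome / censoring."""
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    return tuple(np.random.default_rng(s) for s in children)


def gen_features(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """n x m matrix of unit-variance Gaussian features, block-equicorrelated.

    The covariance is block diagonal: compound symmetry with correlation
    rho inside each block of ``block_len`` features, zero across blocks.
    """
    rng = rng if rng is not None else _rngs(cfg)[0]
    b = cfg.block_len
    cs = np.full((b, b), cfg.rho) + (1.0 - cfg.rho) * np.eye(b)
    L = np.linalg.cholesky(cs)
    E = rng.standard_normal((cfg.n, cfg.n_blocks, b))
    return (E @ L.T).reshape(cfg.n, cfg.m)


def place_true_features(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> TruthSet:
    """Plant m1 true predictors pairwise into m1/2 distinct blocks.

    Coefficients alternate in sign: (-1)^(l+1) * magnitude for
    l = 1..m1.  By default the pairs occupy the first two positions of
    the first m1/2 blocks (reproducible placement); with
    ``randomize_placement`` the blocks and in-block positions are drawn
    from the placement stream.
    """
    ids = cfg.feature_ids()
    half = cfg.m1 // 2
    if cfg.randomize_placement:
        rng = rng if rng is not None else _rngs(cfg)[1]
        blocks = rng.choice(cfg.n_blocks, size=half, replace=False)
        cols = np.concatenate(
            [
                b * cfg.block_len
                + rng.choice(cfg.block_len, size=2, replace=False)
                for b in blocks
            ]
        )
    else:
        cols = np.concatenate(
            [[b * cfg.block_len, b * cfg.block_len + 1] for b in range(half)]
        )
    cols = np.asarray(cols, dtype=np.intp)
    betas = np.array(
        [(-1.0) ** (l + 1) * cfg.beta_magnitude for l in range(1, cfg.m1 + 1)]
    )
    return TruthSet(
        true_ids=[ids[c] for c in cols], true_betas=betas, true_cols=cols
    )


def gen_binary_outcome(
    Z_true: np.ndarray, truth: TruthSet, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli outcomes from the logistic model with zero intercept."""
    Z_true = np.atleast_2d(np.asarray(Z_true, dtype=float))
    if Z_true.shape[1] != len(truth.true_betas):
        raise ValueError("Z_true columns must match the planted coefficients")
    from scipy.special import expit

    p = expit(Z_true @ truth.true_betas)
    return (rng.random(len(p)) < p).astype(np.int64)


def _risk_sd(cfg: SimConfig) -> float:
    """Standard deviation of beta' z under the block-equicorrelation DGP.

    Pairs share a block (covariance rho); different pairs are
    independent, so var = sum beta^2 + 2 rho sum_pairs beta_2l-1 beta_2l.
    """
    betas = np.array(
        [(-1.0) ** (l + 1) * cfg.beta_magnitude for l in range(1, cfg.m1 + 1)]
    )
    var = float(betas @ betas)
    for j in range(0, cfg.m1, 2):
        var += 2.0 * cfg.rho * betas[j] * betas[j + 1]
    return float(np.sqrt(var))


@lru_cache(maxsize=32)
def _calibration_lambdas(h0: float, sigma: float) -> np.ndarray:
    rng = np.random.default_rng(_CALIBRATION_SEED)
    return h0 * np.exp(sigma * rng.standard_normal(_CALIBRATION_DRAWS))


def _censor_frac_uniform(a: float, lam: np.ndarray) -> float:
    """P(T > C) with T ~ Exp(lam), C ~ U(0, a), averaged over lam draws."""
    x = lam * a
    return float(np.mean((1.0 - np.exp(-x)) / x))


def _censor_frac_shifted(a: float, b: float, lam: np.ndarray) -> float:
    """P(T > C) with C ~ U(a, a+b): extra follow-up after the accrual window."""
    x = lam * b
    return float(np.mean(np.exp(-lam * a) * (1.0 - np.exp(-x)) / x))


def calibrate_censoring(
    cfg: SimConfig, target: float | None = None
) -> tuple[float, float | None]:
    """Find the uniform-censoring window achieving the target censoring rate.

    Returns ``(a, None)`` for targets at or above the reference level
    (C ~ U(0, a)), and ``(a, b)`` below it, with ``a`` held at its
    reference-level value and the follow-up ``b`` solved by root-finding
    (C ~ U(a, a+b)).  The censoring fraction is computed by integrating
    the uniform censoring time analytically and Monte-Carlo averaging
    over the (fixed-seed) distribution of the true risk score.
    """
    target = target if target is not None else cfg.censor_target
    if target is None or not (0.0 < target < 1.0):
        raise ValueError("calibration target must lie in (0, 1)")
    lam = _calibration_lambdas(cfg.baseline_hazard, _risk_sd(cfg))

    def solve(fn, lo, hi):
        flo, fhi = fn(lo), fn(hi)
        if flo * fhi > 0:
            raise ValueError(
                "censoring target not bracketed: "
                f"f({lo:.3g})={flo:.4f}, f({hi:.3g})={fhi:.4f}"
            )
        return brentq(fn, lo, hi, xtol=1e-10, rtol=1e-12)

    ref = max(target, REFERENCE_CENSORING)
    a = solve(lambda x: _censor_frac_uniform(x, lam) - ref, 1e-8, 1e8)
    if target >= REFERENCE_CENSORING:
        return float(a), None
    floor = float(np.mean(np.exp(-lam * a)))   # b -> 0 limit of the fraction
    if target >= floor:
        raise ValueError(
            f"target {target} is not reachable with accrual a={a:.3g}: even "
            f"immediate post-accrual censoring leaves only {floor:.3f} censored"
        )
    b = solve(lambda x: _censor_frac_shifted(a, x, lam) - target, 1e-8, 1e8)
    return float(a), float(b)


def gen_survival_outcome(
    Z_true: np.ndarray,
    truth: TruthSet,
    cfg: SimConfig,
    rng: np.random.Generator,
    rng_censor: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(observed time, event indicator) under the proportional-hazards DGP.

    Event times are exponential with rate h0 * exp(beta' z) (inverse
    transform); censoring times are uniform per the calibrated scheme in
    ``cfg``; censoring is independent of survival given the covariates.
    Passing a separate ``rng_censor`` keeps the latent event times
    invariant across censoring schemes.
    """
    Z_true = np.atleast_2d(np.asarray(Z_true, dtype=float))
    if Z_true.shape[1] != len(truth.true_betas):
        raise ValueError("Z_true columns must match the planted coefficients")
    rng_censor = rng_censor if rng_censor is not None else rng
    lam = cfg.baseline_hazard * np.exp(Z_true @ truth.true_betas)
    T = rng.exponential(scale=1.0, size=len(lam)) / lam
    if cfg.censor_target is None:
        return T, np.ones(len(T), dtype=np.int64)
    if cfg.censor_a is None or (
        cfg.censor_target < REFERENCE_CENSORING and cfg.censor_b is None
    ):
        raise ValueError(
            "censoring window not calibrated: call calibrate_censoring() and "
            "store the result in censor_a (and censor_b)"
        )
    if cfg.censor_b is None:
        C = rng_censor.uniform(0.0, cfg.censor_a, size=len(T))
    else:
        C = rng_censor.uniform(
            cfg.censor_a, cfg.censor_a + cfg.censor_b, size=len(T)
        )
    event = (T <= C).astype(np.int64)
    return np.minimum(T, C), event


def holdout_split(
    n: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random 50-50 split; odd n gives training the extra subject."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = (n + 1) // 2
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def simulate_dataset(cfg: SimConfig) -> tuple[Dataset, TruthSet]:
    """One full simulated dataset plus its planted truth.

    Features, outcome, and censoring use independent streams spawned from
    ``cfg.seed``, so e.g. two censoring levels run with the same seed
    share the same covariates and latent event times.  The censoring
    window is calibrated automatically (and cached) when needed.
    """
    rng_x, rng_place, rng_out, rng_cens = _rngs(cfg)
    X = gen_features(cfg, rng_x)
    truth = place_true_features(cfg, rng_place)
    Z = X[:, truth.true_cols]
    if cfg.family == "binary":
        y = gen_binary_outcome(Z, truth, rng_out)
        ds = Dataset(X=X, feature_ids=cfg.feature_ids(), y=y)
        return ds, truth
    if cfg.censor_target is not None and cfg.censor_a is None:
        a, b = calibrate_censoring(cfg)
        cfg = replace(cfg, censor_a=a, censor_b=b)
    time, event = gen_survival_outcome(Z, truth, cfg, rng_out, rng_cens)
    ds = Dataset(X=X, feature_ids=cfg.feature_ids(), time=time, event=event)
    return ds, truth
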