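"""Repeated sieving: blockwise stepwise selection over feature permutations.

With tens of thousands of candidate features, an unpenalized stepwise
search over all of them at once is computationally hopeless.  Repeated
sieving instead partitions the features into many small blocks (default
50 features), runs the significance-threshold stepwise search within
each block, and keeps the union of the per-block selections.  Because
two correlated true predictors must share a block to be estimated
jointly without bias, the partition is re-drawn from random feature
permutations P times and the per-permutation selections pooled; the
final prediction model is then a stepwise fit on the pooled candidates
with (usually stricter) final thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import Dataset
from .stepwise import (
    SelectionResult,
    StepwiseConfig,
    _make_engine,
    forward_stepwise,
)

__all__ = ["SieveConfig", "SieveReport", "partition_blocks",
           "sieve_one_permutation", "repeated_sieving"]

log = logging.getLogger(__name__)


@dataclass
class SieveConfig:
    """Tuning parameters of one repeated-sieving run.

    ``alpha_in``/``alpha_out`` gate the within-block stepwise searches;
    ``final_alpha_in``/``final_alpha_out`` gate the final model fitted on
    the pooled candidates.  If the pool exceeds ``pool_cap`` after P
    permutations and rounds remain, a further sieving round (same P, same
    thresholds) is applied to the pooled features only.  The first
    permutation of each round uses the unpermuted feature order; set
    ``identity_first=False`` to randomize it as well.
    """

    block_size: int = 50
    permutations: int = 100
    alpha_in: float = 0.01
    alpha_out: float = 0.02
    final_alpha_in: float = 0.0025
    final_alpha_out: float = 0.005
    pool_cap: int = 1000
    max_rounds: int = 2
    seed: int = 0
    identity_first: bool = True
    max_selected: int = 30

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be at least 2")
        if self.permutations < 1:
            raise ValueError("need at least one permutation")
        if self.alpha_out < self.alpha_in or self.final_alpha_out < self.final_alpha_in:
            raise ValueError("deletion threshold must be >= insertion threshold")
        if self.pool_cap < 1 or self.max_rounds < 1:
            raise ValueError("pool_cap and max_rounds must be positive")


@dataclass
class SieveReport:
    """Everything a repeated-sieving run produced, reproducibly.

    ``cumulative_pool_sizes`` holds, per round, the size of the pooled
    candidate set after each permutation (non-decreasing by
    construction); ``pool`` is the final pooled candidate set the last
    stepwise ran on.
    """

    final: SelectionResult
    pool: list[str]
    cumulative_pool_sizes: list[list[int]]
    round_pool_sizes: list[int]
    seed: int
    config: SieveConfig

    @property
    def selected(self) -> list[str]:
        return self.final.selected

    def to_text(self) -> str:
        lines = ["# repeated sieving report", f"seed: {self.seed}"]
        for r, sizes in enumerate(self.cumulative_pool_sizes, start=1):
            lines.append(f"round {r}: pool sizes per permutation: {sizes}")
        lines.append(f"pooled candidates: {len(self.pool)}")
        lines.append(f"final selections: {len(self.final.selected)}")
        fit = self.final.fit
        if fit is not None and fit.feature_ids:
            lines.append("feature\tcoef\tse\tp_value")
            for fid, c, s, p in zip(fit.feature_ids, fit.coef, fit.se, fit.p_values):
                lines.append(f"{fid}\t{c:.6g}\t{s:.6g}\t{p:.3g}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        fit = self.final.fit
        payload = {
            "seed": self.seed,
            "config": asdict(self.config),
            "cumulative_pool_sizes": self.cumulative_pool_sizes,
            "round_pool_sizes": self.round_pool_sizes,
            "pool": self.pool,
            "selected": self.final.selected,
            "trace": self.final.trace,
            "fit": None
            if fit is None
            else {
                "feature_ids": list(fit.feature_ids),
                "coef": fit.coef.tolist(),
                "se": fit.se.tolist(),
                "p_values": fit.p_values.tolist(),
                "intercept": fit.intercept,
                "loglik": fit.loglik,
                "converged": fit.converged,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def partition_blocks(feature_order: Sequence[str], m0: int) -> list[list[str]]:
    """Split an ordered feature list into contiguous blocks of size m0.

    A remainder shorter than ``m0`` forms a final smaller block (features
    are never dropped).  ``m0`` larger than the list yields one block
    with a warning.
    """
    feats = list(feature_order)
    m = len(feats)
    if m == 0:
        raise ValueError("feature_order is empty")
    if m0 > m:
        log.warning("block size %d exceeds feature count %d; using one block", m0, m)
        return [feats]
    return [feats[i : i + m0] for i in range(0, m, m0)]


def sieve_one_permutation(
    data: Dataset,
    rng: np.random.Generator | None,
    config: SieveConfig,
    candidate_ids: Sequence[str] | None = None,
    identity: bool = False,
    _engine=None,
) -> set[str]:
    """Sieve one (possibly identity) permutation of the candidate features.

    Draws a uniform random permutation of the candidate ids (or keeps the
    original order when ``identity``), partitions it into blocks, runs
    the within-block stepwise search in each, and returns the union of
    the per-block selections.
    """
    ids = list(candidate_ids) if candidate_ids is not None else list(data.feature_ids)
    if identity:
        order = ids
    else:
        if rng is None:
            raise ValueError("a random generator is required unless identity=True")
        order = [ids[j] for j in rng.permutation(len(ids))]
    sw = StepwiseConfig(
        alpha_in=config.alpha_in,
        alpha_out=config.alpha_out,
        family=data.family,
        max_selected=config.max_selected,
    )
    engine = _engine if _engine is not None else _make_engine(data)
    picked: set[str] = set()
    for block in partition_blocks(order, config.block_size):
        res = forward_stepwise(data, block, sw, _engine=engine)
        picked.update(res.selected)
    return picked


def repeated_sieving(data: Dataset, config: SieveConfig) -> SieveReport:
    """Run the full repeated-sieving pipeline on one training dataset.

    Each permutation gets an independent random stream spawned from the
    master seed, so results are reproducible and permutations could be
    evaluated in parallel without changing the output.
    """
    engine = _make_engine(data)
    pool_ids = list(data.feature_ids)
    cumulative: list[list[int]] = []
    round_sizes: list[int] = []
    master = np.random.SeedSequence(config.seed)

    for rnd in range(config.max_rounds):
        streams = master.spawn(config.permutations)
        pool: set[str] = set()
        sizes: list[int] = []
        for p, ss in enumerate(streams):
            identity = config.identity_first and p == 0
            rng = np.random.default_rng(ss)
            pool |= sieve_one_permutation(
                data, rng, config, candidate_ids=pool_ids,
                identity=identity, _engine=engine,
            )
            sizes.append(len(pool))
        cumulative.append(sizes)
        round_sizes.append(len(pool))
        pool_ids = sorted(pool, key=data.col)      # deterministic final order
        log.info("sieving round %d pooled %d candidates", rnd + 1, len(pool_ids))
        if len(pool_ids) <= config.pool_cap or rnd == config.max_rounds - 1:
            break

    if not pool_ids:
        log.warning("empty candidate pool after sieving; returning empty model")
        final = SelectionResult(selected=[], fit=None, trace=[])
    else:
        sw = StepwiseConfig(
            alpha_in=config.final_alpha_in,
            alpha_out=config.final_alpha_out,
            family=data.family,
            max_selected=config.max_selected,
        )
        final = forward_stepwise(data, pool_ids, sw, _engine=engine)
    return SieveReport(
        final=final,
        pool=pool_ids,
        cumulative_pool_sizes=cumulative,
        round_pool_sizes=round_sizes,
        seed=config.seed,
        config=config,
    )
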