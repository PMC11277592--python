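"""Rectangular feature tables with a binary or survival outcome.

The on-disk format is plain delimited text: one header row of stable
feature identifiers, one row per subject, plus either a binary outcome
column or a (time, event) column pair.  Fitted models persist as
structured JSON text (feature ids + coefficients + family + metadata)
so they remain portable and auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regression import FitResult

__all__ = [
    "Dataset",
    "load_dataset",
    "save_dataset",
    "PersistedModel",
    "save_model",
    "load_model",
]


@dataclass
class Dataset:
    """Subjects x features matrix together with one outcome.

    Exactly one of the two outcome families must be present:

    * binary: ``y`` with values in {0, 1};
    * survival: ``time`` (> 0 observed times) and ``event`` (1 = event
      observed, 0 = censored).
    """

    X: np.ndarray
    feature_ids: list[str]
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix (subjects x features)")
        if np.isnan(self.X).any():
            bad = np.unique(np.nonzero(np.isnan(self.X))[0])
            raise ValueError(f"missing values in rows {bad.tolist()}")
        n, m = self.X.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != m:
            raise ValueError("feature_ids length does not match X columns")
        dupes = pd.Index(self.feature_ids)
        if dupes.has_duplicates:
            raise ValueError(
                "duplicate feature ids: "
                + ", ".join(sorted(set(dupes[dupes.duplicated()])))
            )
        has_binary = self.y is not None
        has_surv = self.time is not None or self.event is not None
        if has_binary == has_surv:
            raise ValueError("provide exactly one outcome: y, or (time, event)")
        if has_binary:
            self.y = np.asarray(self.y)
            if len(self.y) != n:
                raise ValueError("y length mismatch")
            if not np.isin(self.y, (0, 1)).all():
                raise ValueError("binary outcome must be coded 0/1")
            self.y = self.y.astype(np.int64)
        else:
            if self.time is None or self.event is None:
                raise ValueError("survival outcome needs both time and event")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event)
            if len(self.time) != n or len(self.event) != n:
                raise ValueError("time/event length mismatch")
            if not (self.time > 0).all():
                raise ValueError("observed times must be strictly positive")
            if not np.isin(self.event, (0, 1)).all():
                raise ValueError("event indicator must be coded 0/1")
            self.event = self.event.astype(np.int64)
        self._index = {f: j for j, f in enumerate(self.feature_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def family(self) -> str:
        return "logistic" if self.y is not None else "cox"

    def col(self, feature_id: str) -> int:
        try:
            return self._index[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def columns(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Covariate sub-matrix for the given ids, in the given order."""
        idx = [self.col(f) for f in feature_ids]
        return self.X[:, idx]

    def subset(self, rows: Sequence[int]) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(
            X=self.X[rows],
            feature_ids=list(self.feature_ids),
            y=None if self.y is None else self.y[rows],
            time=None if self.time is None else self.time[rows],
            event=None if self.event is None else self.event[rows],
        )


def load_dataset(
    path: str | Path,
    outcome: str | None = None,
    time: str | None = None,
    event: str | None = None,
    sep: str | None = None,
) -> Dataset:
    """Read a delimited text table into a :class:`Dataset`.

    Either ``outcome`` (binary column name) or both ``time`` and ``event``
    must name columns of the file; every remaining column is a feature.
    The delimiter is sniffed when ``sep`` is not given.
    """
    path = Path(path)
    if (outcome is None) == (time is None and event is None):
        raise ValueError("name either a binary outcome column or time+event columns")
    if (time is None) != (event is None):
        raise ValueError("survival outcome needs both time and event column names")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # pandas mangles duplicate headers ("a", "a.1"); inspect the raw header
    header = (
        pd.read_csv(path, sep=sep, header=None, nrows=1)
        .iloc[0]
        .astype(str)
        .tolist()
    )
    seen: dict[str, int] = {}
    for name in header:
        seen[name] = seen.get(name, 0) + 1
    dupes = sorted(name for name, cnt in seen.items() if cnt > 1)
    if dupes:
        raise ValueError("duplicate column names: " + ", ".join(dupes))
    raw = pd.read_csv(path, sep=sep)
    wanted = [c for c in (outcome, time, event) if c is not None]
    missing = [c for c in wanted if c not in raw.columns]
    if missing:
        raise ValueError("missing outcome column(s): " + ", ".join(missing))
    feats = raw.drop(columns=wanted)
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & ~feats.isna()
    if bad_cells.any().any():
        cols = list(feats.columns[bad_cells.any(axis=0)])
        raise ValueError("non-numeric values in feature column(s): " + ", ".join(cols))
    if numeric.isna().any().any():
        rows = list(numeric.index[numeric.isna().any(axis=1)])
        raise ValueError(f"missing feature values in rows {rows}")
    kwargs = {}
    if outcome is not None:
        kwargs["y"] = pd.to_numeric(raw[outcome]).to_numpy()
    else:
        kwargs["time"] = pd.to_numeric(raw[time]).to_numpy()
        kwargs["event"] = pd.to_numeric(raw[event]).to_numpy()
    return Dataset(
        X=numeric.to_numpy(dtype=float),
        feature_ids=list(feats.columns),
        **kwargs,
    )


def save_dataset(
    ds: Dataset,
    path: str | Path,
    outcome: str = "y",
    time: str = "time",
    event: str = "event",
    sep: str = ",",
) -> None:
    """Write the dataset as delimited text (outcome columns first)."""
    frame = pd.DataFrame(ds.X, columns=ds.feature_ids)
    if ds.family == "logistic":
        frame.insert(0, outcome, ds.y)
    else:
        frame.insert(0, time, ds.time)
        frame.insert(1, event, ds.event)
    frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "repsieve-model"


@dataclass
class PersistedModel:
    """A fitted prediction model reloaded from its JSON artifact."""

    family: str
    feature_ids: list[str]
    coef: np.ndarray
    intercept: float | None = None
    meta: dict = field(default_factory=dict)

    def risk_scores(self, ds: Dataset) -> np.ndarray:
        """Linear predictor beta' Z on a new dataset (no intercept term)."""
        missing = [f for f in self.feature_ids if f not in ds._index]
        if missing:
            raise KeyError(
                "dataset is missing model feature(s): " + ", ".join(missing)
            )
        if not self.feature_ids:
            return np.zeros(ds.n)
        return ds.columns(self.feature_ids) @ self.coef


def save_model(fit: FitResult, path: str | Path, meta: dict | None = None) -> None:
    payload = {
        "format": _MODEL_FORMAT,
        "version": 1,
        "family": fit.family,
        "intercept": fit.intercept,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "features": [
            {
                "id": fid,
                "coef": float(c),
                "se": None if not np.isfinite(s) else float(s),
                "p_value": None if not np.isfinite(p) else float(p),
            }
            for fid, c, s, p in zip(
                fit.feature_ids, fit.coef, fit.se, fit.p_values
            )
        ],
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> PersistedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path} is not a persisted model artifact")
    feats = payload["features"]
    return PersistedModel(
        family=payload["family"],
        feature_ids=[f["id"] for f in feats],
        coef=np.array([f["coef"] for f in feats], dtype=float),
        intercept=payload.get("intercept"),
        meta=payload.get("meta", {}),
    )
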