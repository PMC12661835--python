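"""Schema-typed tabular datasets with a binary outcome.

Every stage of the augmentation pipeline exchanges :class:`Dataset` objects:
a pandas DataFrame whose columns are declared in a :class:`Schema` as numeric
or categorical predictors plus exactly one binary categorical outcome.  The
module also provides the shared plumbing — CSV/YAML round-tripping,
outcome-stratified splitting, and smoothed target encoding of categoricals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = "__missing__"
"""Sentinel level used for missing categorical cells."""


class SchemaError(ValueError):
    """Raised when data violate the declared schema."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single column.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : {"numeric", "categorical"}
    levels : tuple of str
        Ordered category labels; empty for numerics.  For the outcome the
        second level is the positive class.
    role : {"predictor", "outcome"}
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    role: str = "predictor"

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in ("predictor", "outcome"):
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind == "categorical":
            if len(set(self.levels)) < 2:
                raise SchemaError(
                    f"categorical {self.name!r} needs >=2 distinct levels"
                )
        elif self.levels:
            raise SchemaError(f"numeric {self.name!r} must not declare levels")


@dataclass(frozen=True)
class Schema:
    """Ordered collection of :class:`VariableSpec` with one binary outcome."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        outcomes = [v for v in self.variables if v.role == "outcome"]
        if len(outcomes) != 1:
            raise SchemaError("schema must declare exactly one outcome")
        out = outcomes[0]
        if out.kind != "categorical" or len(out.levels) != 2:
            raise SchemaError("outcome must be categorical with exactly 2 levels")

    @property
    def outcome(self) -> VariableSpec:
        return next(v for v in self.variables if v.role == "outcome")

    @property
    def predictors(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.role == "predictor")

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    "levels": list(v.levels),
                    "role": v.role,
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        return cls(
            tuple(
                VariableSpec(
                    name=v["name"],
                    kind=v["kind"],
                    levels=tuple(v.get("levels") or ()),
                    role=v.get("role", "predictor"),
                )
                for v in d["variables"]
            )
        )


@dataclass
class Dataset:
    """A rectangular table conforming to a :class:`Schema`.

    ``df`` keeps categoricals as strings and numerics as float64; the outcome
    column never contains missing cells (rows with missing outcome are
    dropped at load time).
    """

    schema: Schema
    df: pd.DataFrame
    id: str = "dataset"

    def __post_init__(self) -> None:
        self.df = coerce_frame(self.df, self.schema)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def outcome01(self) -> np.ndarray:
        """Outcome as a {0,1} vector; the second declared level is positive."""
        out = self.schema.outcome
        return (self.df[out.name].to_numpy() == out.levels[1]).astype(np.int64)

    def predictor_frame(self) -> pd.DataFrame:
        return self.df[[v.name for v in self.schema.predictors]]

    def prevalence(self) -> float:
        return float(self.outcome01().mean())

    def subset(self, index: Sequence[int] | np.ndarray, id: str | None = None) -> "Dataset":
        sub = self.df.iloc[np.asarray(index)].reset_index(drop=True)
        return Dataset(self.schema, sub, id=id or self.id)

    def content_hash(self) -> str:
        """Stable hash of cell contents (used to assert a fixed test split)."""
        h = hashlib.sha256()
        h.update(self.df.to_csv(index=False).encode())
        return h.hexdigest()


@dataclass
class SplitPair:
    train: Dataset
    test: Dataset


def coerce_frame(df: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Coerce a raw frame to schema types, validating levels.

    Rows with a missing outcome are dropped; missing categorical predictors
    become the :data:`MISSING` sentinel level; missing numerics stay NaN.
    """
    cols = [v.name for v in schema.variables]
    missing_cols = set(cols) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"columns absent from data: {sorted(missing_cols)}")
    out = pd.DataFrame(index=df.index)
    for v in schema.variables:
        col = df[v.name]
        if v.kind == "numeric":
            try:
                out[v.name] = pd.to_numeric(col, errors="raise").astype(np.float64)
            except (ValueError, TypeError) as e:
                raise SchemaError(f"unparseable numeric cell in {v.name!r}: {e}")
        else:
            s = col.astype("object").copy()
            s[pd.isna(s)] = np.nan
            s = s.where(pd.isna(s), s.astype(str))
            if v.role == "outcome":
                keep = ~pd.isna(s)
                out = out.loc[keep]
                s = s.loc[keep]
            else:
                s = s.where(~pd.isna(s), MISSING)
            allowed = set(v.levels) | {MISSING}
            bad = set(s.unique()) - allowed
            if bad:
                raise SchemaError(
                    f"unknown levels {sorted(bad)} for {v.name!r}; "
                    f"declared {list(v.levels)}"
                )
            out[v.name] = s
    return out[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def read_schema(path: str | Path) -> Schema:
    with open(path) as fh:
        return Schema.from_dict(yaml.safe_load(fh))


def write_schema(schema: Schema, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema.to_dict(), fh, sort_keys=False)


def read_dataset(path: str | Path, schema_path: str | Path, id: str | None = None) -> Dataset:
    """Load a CSV against its YAML schema sidecar.

    The CSV must be comma-separated UTF-8 with a header row whose names match
    the schema; undeclared category labels are rejected.
    """
    schema = read_schema(schema_path)
    df = pd.read_csv(path, dtype="object", keep_default_na=True)
    return Dataset(schema, df, id=id or Path(path).stem)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    df = ds.df.copy()
    for v in ds.schema.variables:
        if v.kind == "numeric":
            df[v.name] = df[v.name].map(lambda x: "" if pd.isna(x) else repr(float(x)))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Splitting


def split_population(
    pop: Dataset, train_fraction: float = 0.7, seed: int = 0
) -> SplitPair:
    """Outcome-stratified train/test split (default 70%:30%).

    Deterministic for a fixed seed; each outcome class is split at the
    configured fraction independently, so train and test prevalences match
    the population's.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = pop.outcome01()
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if len(members) < 2:
            raise ValueError(f"outcome class {cls} has <2 rows; cannot stratify")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return SplitPair(
        train=pop.subset(tr, id=f"{pop.id}:train"),
        test=pop.subset(te, id=f"{pop.id}:test"),
    )


def stratified_sample(
    ds: Dataset, n: int, seed: int, replace: bool = False
) -> Dataset:
    """Outcome-stratified random sample of ``n`` rows without replacement."""
    if n > len(ds) and not replace:
        raise ValueError(f"cannot draw {n} rows from {len(ds)} without replacement")
    y = ds.outcome01()
    prev = y.mean()
    n_pos = int(round(n * prev))
    n_pos = min(max(n_pos, 1), n - 1)
    n_neg = n - n_pos
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if (len(pos) < n_pos or len(neg) < n_neg) and not replace:
        raise ValueError("a class is too small for the requested stratified draw")
    idx = np.concatenate(
        [
            rng.choice(pos, size=n_pos, replace=replace),
            rng.choice(neg, size=n_neg, replace=replace),
        ]
    )
    return ds.subset(np.sort(idx), id=f"{ds.id}:n{n}")


# ---------------------------------------------------------------------------
# Target encoding


@dataclass
class TargetEncoder:
    """Smoothed target (mean) encoding of categorical predictors.

    Each level of a categorical predictor is replaced by a shrunken positive
    rate ``(count * level_mean + smoothing * global_mean) / (count +
    smoothing)`` computed on the fitting data only; numerics pass through
    unchanged.  Unseen levels at transform time map to the global mean.
    """

    smoothing: float = 10.0
    mappings_: dict[str, dict[str, float]] = field(default_factory=dict)
    global_mean_: float | None = None
    schema_: Schema | None = None

    def fit(self, train: Dataset) -> "TargetEncoder":
        y = train.outcome01().astype(float)
        self.global_mean_ = float(y.mean())
        self.schema_ = train.schema
        self.mappings_ = {}
        for v in train.schema.predictors:
            if v.kind != "categorical":
                continue
            col = train.df[v.name]
            grouped = pd.Series(y).groupby(col.to_numpy(), sort=False)
            counts = grouped.size()
            means = grouped.mean()
            enc = (counts * means + self.smoothing * self.global_mean_) / (
                counts + self.smoothing
            )
            self.mappings_[v.name] = enc.to_dict()
        return self

    def transform(self, ds: Dataset) -> np.ndarray:
        """Numeric matrix (rows x predictors), schema order."""
        if self.global_mean_ is None or self.schema_ is None:
            raise RuntimeError("TargetEncoder used before fit")
        cols = []
        for v in self.schema_.predictors:
            col = ds.df[v.name]
            if v.kind == "numeric":
                cols.append(col.to_numpy(dtype=np.float64))
            else:
                mapping = self.mappings_[v.name]
                cols.append(
                    col.map(lambda lv: mapping.get(lv, self.global_mean_)).to_numpy(
                        dtype=np.float64
                    )
                )
        return np.column_stack(cols)

    def fit_transform(self, train: Dataset) -> np.ndarray:
        return self.fit(train).transform(train)


def target_encode(
    train: Dataset, apply_to: Dataset, smoothing: float = 10.0
) -> tuple[np.ndarray, TargetEncoder]:
    """Fit on ``train`` only, encode ``apply_to``; returns matrix + encoder."""
    enc = TargetEncoder(smoothing=smoothing).fit(train)
    return enc.transform(apply_to), enc
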