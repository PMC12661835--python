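"""Generative models used for augmentation.

Four synthesizers share one fit/sample contract: a non-parametric bootstrap
(whole-row resampling with replacement — the "larger sample size without new
diversity" control), sequential decision trees, a Bayesian network, and an
adapter hook for external deep tabular models (CTGAN/TVAE-style) invoked
through CSV files.  ``augment`` concatenates a base dataset with ``n'``
sampled rows, yielding the n = n0 + n' training set the workload consumes.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import bayesnet, seqtrees
from .core import Dataset, Schema, read_dataset, write_dataset, write_schema

GENERATOR_NAMES = ("bootstrap", "seq_trees", "bayes_net")


@dataclass
class GeneratorModel:
    """A fitted synthesizer.

    ``sample`` output always conforms to the training schema, and categorical
    samples only emit levels observed in the training data.
    """

    method: str
    schema: Schema
    fitted_state: object
    seed: int = 0

    def sample(self, m: int, seed: int | None = None) -> Dataset:
        return sample(self, m, seed if seed is not None else self.seed)


def fit_bootstrap(base: Dataset, seed: int = 0) -> GeneratorModel:
    """Whole-row uniform resampling with replacement."""
    if len(base) < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    return GeneratorModel("bootstrap", base.schema, fitted_state=base.df.copy(), seed=seed)


def fit_seq_trees(
    base: Dataset,
    min_leaf: int = 5,
    max_depth: int = 12,
    order: tuple[str, ...] | None = None,
    seed: int = 0,
) -> GeneratorModel:
    """Sequential CART synthesis (first variable from its marginal)."""
    state = seqtrees.fit_seq_trees_state(
        base, min_leaf=min_leaf, max_depth=max_depth, order=order, seed=seed
    )
    return GeneratorModel("seq_trees", base.schema, fitted_state=state, seed=seed)


def fit_bayes_net(
    base: Dataset,
    max_parents: int = 3,
    prior_strength: float = 1.0,
    n_bins: int = 5,
    seed: int = 0,
) -> GeneratorModel:
    """Hill-climb BIC structure learning + Dirichlet-smoothed CPTs."""
    state = bayesnet.fit_bayes_net_state(
        base, max_parents=max_parents, prior_strength=prior_strength, n_bins=n_bins
    )
    return GeneratorModel("bayes_net", base.schema, fitted_state=state, seed=seed)


@dataclass
class AdapterSpec:
    """External synthesizer invoked as a subprocess over CSV files.

    The command receives ``{train} {schema} {m} {seed} {out}`` placeholders
    and must write a schema-conformant CSV to ``{out}``.
    """

    command: list[str]


def fit_adapter(base: Dataset, adapter: AdapterSpec, seed: int = 0) -> GeneratorModel:
    return GeneratorModel(
        "adapter", base.schema, fitted_state=(adapter, base.df.copy()), seed=seed
    )


def _sample_adapter(model: GeneratorModel, m: int, seed: int) -> pd.DataFrame:
    adapter, train_df = model.fitted_state
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        train_path, schema_path, out_path = tmp / "train.csv", tmp / "schema.yaml", tmp / "out.csv"
        write_dataset(Dataset(model.schema, train_df), train_path)
        write_schema(model.schema, schema_path)
        cmd = [
            arg.format(train=train_path, schema=schema_path, m=m, seed=seed, out=out_path)
            for arg in adapter.command
        ]
        subprocess.run(cmd, check=True)
        return read_dataset(out_path, schema_path).df


def sample(model: GeneratorModel, m: int, seed: int = 0) -> Dataset:
    """Draw exactly ``m`` schema-conformant rows; deterministic per seed."""
    if m < 1:
        raise ValueError("sample size m must be >= 1")
    rng = np.random.default_rng(seed)
    if model.method == "bootstrap":
        df: pd.DataFrame = model.fitted_state
        idx = rng.integers(0, len(df), size=m)
        out = df.iloc[idx].reset_index(drop=True)
    elif model.method == "seq_trees":
        out = seqtrees.sample_seq_trees(model.fitted_state, m, rng)
    elif model.method == "bayes_net":
        out = bayesnet.sample_bayes_net(model.fitted_state, m, rng)
    elif model.method == "adapter":
        out = _sample_adapter(model, m, seed)
    else:
        raise ValueError(f"unknown generator method {model.method!r}")
    return Dataset(model.schema, out, id=f"synthetic-{model.method}")


def augment(base: Dataset, model: GeneratorModel, n_prime: int, seed: int = 0) -> Dataset:
    """Concatenate ``base`` with ``n_prime`` synthetic rows (base rows first)."""
    if n_prime < 1:
        raise ValueError("n_prime must be >= 1; use the base dataset directly")
    if model.schema != base.schema:
        raise ValueError("generator schema does not match base schema")
    synth = sample(model, n_prime, seed)
    df = pd.concat([base.df, synth.df], ignore_index=True)
    return Dataset(base.schema, df, id=f"{base.id}+{model.method}{n_prime}")


FITTERS: dict[str, Callable[..., GeneratorModel]] = {
    "bootstrap": fit_bootstrap,
    "seq_trees": fit_seq_trees,
    "bayes_net": fit_bayes_net,
}


def fit_generator(name: str, base: Dataset, seed: int = 0, **kwargs) -> GeneratorModel:
    if name not in FITTERS:
        raise ValueError(f"unknown generator {name!r}; choose from {sorted(FITTERS)}")
    return FITTERS[name](base, seed=seed, **kwargs)
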