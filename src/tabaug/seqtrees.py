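"""Sequential decision-tree synthesis.

Variables are synthesized one at a time in a fixed order: the first from its
empirical marginal, each subsequent variable from a CART tree fitted on the
preceding variables (classification tree for categoricals, regression tree
for numerics).  At sampling time the already-synthesized prefix routes each
record to a leaf; categoricals are drawn from the leaf's class frequencies
and numerics uniformly from the leaf's pool of observed training values, so
the synthesizer never invents values outside the observed support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .core import MISSING, Dataset, Schema, VariableSpec


def _encode_predictors(
    df: pd.DataFrame, specs: list[VariableSpec]
) -> np.ndarray:
    """One-hot categoricals / raw numerics for the conditioning columns."""
    cols = []
    for v in specs:
        s = df[v.name]
        if v.kind == "numeric":
            x = s.to_numpy(dtype=float)
            cols.append(np.nan_to_num(x, nan=0.0)[:, None])
            cols.append(np.isnan(x).astype(float)[:, None])
        else:
            levels = list(v.levels) + [MISSING]
            codes = pd.Categorical(s, categories=levels).codes
            onehot = np.zeros((len(s), len(levels)))
            onehot[np.arange(len(s)), codes] = 1.0
            cols.append(onehot)
    return np.hstack(cols) if cols else np.zeros((len(df), 0))


@dataclass
class _VariableModel:
    spec: VariableSpec
    tree: object | None  # None for the first variable (marginal)
    # leaf id -> array of observed values (numeric) or (levels, probs)
    pools: dict = field(default_factory=dict)
    marginal_values: np.ndarray | None = None
    marginal_probs: np.ndarray | None = None


@dataclass
class SeqTreesState:
    order: tuple[str, ...]
    models: list[_VariableModel]
    schema: Schema
    min_leaf: int
    max_depth: int


def fit_seq_trees_state(
    base: Dataset,
    min_leaf: int = 5,
    max_depth: int = 12,
    order: tuple[str, ...] | None = None,
    seed: int = 0,
) -> SeqTreesState:
    if len(base) < 2 * min_leaf:
        raise ValueError("base dataset too small for the configured min_leaf")
    schema = base.schema
    order = order or tuple(v.name for v in schema.variables)
    df = base.df
    models: list[_VariableModel] = []
    for j, name in enumerate(order):
        spec = schema[name]
        target = df[name]
        if j == 0:
            vc = target.value_counts(sort=False) if spec.kind == "categorical" else None
            if spec.kind == "categorical":
                m = _VariableModel(
                    spec,
                    tree=None,
                    marginal_values=vc.index.to_numpy(),
                    marginal_probs=(vc / vc.sum()).to_numpy(),
                )
            else:
                m = _VariableModel(spec, tree=None, marginal_values=target.to_numpy(dtype=float))
            models.append(m)
            continue
        preds = [schema[n] for n in order[:j]]
        X = _encode_predictors(df, preds)
        if spec.kind == "categorical":
            tree = DecisionTreeClassifier(
                min_samples_leaf=min_leaf, max_depth=max_depth, random_state=seed
            )
            with warnings.catch_warnings():
                # high-cardinality categorical targets trip sklearn's
                # "could be regression" heuristic; the target is categorical
                warnings.simplefilter("ignore", UserWarning)
                tree.fit(X, target.to_numpy())
            models.append(_VariableModel(spec, tree=tree))
        else:
            y = target.to_numpy(dtype=float)
            ok = ~np.isnan(y)
            tree = DecisionTreeRegressor(
                min_samples_leaf=min_leaf, max_depth=max_depth, random_state=seed
            )
            tree.fit(X[ok], y[ok])
            leaves = tree.apply(X[ok])
            pools: dict[int, np.ndarray] = {}
            for leaf in np.unique(leaves):
                pools[int(leaf)] = y[ok][leaves == leaf]
            models.append(_VariableModel(spec, tree=tree, pools=pools))
    return SeqTreesState(order=order, models=models, schema=schema,
                         min_leaf=min_leaf, max_depth=max_depth)


def sample_seq_trees(state: SeqTreesState, m: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``m`` synthetic rows by ancestral sampling along the order."""
    out = pd.DataFrame(index=range(m))
    for j, model in enumerate(state.models):
        spec = model.spec
        if model.tree is None:
            if spec.kind == "categorical":
                draws = rng.choice(model.marginal_values, size=m, p=model.marginal_probs)
            else:
                draws = rng.choice(model.marginal_values, size=m, replace=True)
            out[spec.name] = draws
            continue
        preds = [state.schema[n] for n in state.order[:j]]
        X = _encode_predictors(out, preds)
        leaves = model.tree.apply(X)
        values = np.empty(m, dtype=object if spec.kind == "categorical" else float)
        if spec.kind == "categorical":
            classes = model.tree.classes_
            # leaf class frequencies from the fitted tree's value counts
            node_counts = model.tree.tree_.value[leaves, 0, :]
            probs = node_counts / node_counts.sum(axis=1, keepdims=True)
            u = rng.random(m)
            cum = np.cumsum(probs, axis=1)
            idx = (u[:, None] > cum).sum(axis=1)
            values[:] = classes[idx]
        else:
            for leaf in np.unique(leaves):
                mask = leaves == leaf
                pool = model.pools[int(leaf)]
                values[mask] = rng.choice(pool, size=mask.sum(), replace=True)
        out[spec.name] = values
    return out[[v.name for v in state.schema.variables]]
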