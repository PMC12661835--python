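"""Bayesian-network synthesis over discretized variables.

Structure is learned by greedy hill climbing from an empty graph over
add/remove/reverse arc moves maximizing the BIC score, subject to acyclicity
and a parent limit.  Numerics are discretized into equal-frequency bins and
back-transformed at sampling time by a uniform draw within the sampled bin.
Conditional probability tables are posterior means under a symmetric
Dirichlet prior, so every CPT row sums to one and unseen parent
configurations fall back to a uniform row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import Dataset, Schema


@dataclass
class _Node:
    name: str
    kind: str
    levels: list  # observed discrete levels (bin indices for numerics)
    bin_edges: np.ndarray | None = None  # numerics only


@dataclass
class BayesNetState:
    dag: nx.DiGraph
    nodes: dict[str, _Node]
    cpts: dict[str, dict[tuple, np.ndarray]]  # var -> parent config -> probs
    order: list[str]  # topological
    schema: Schema
    prior_strength: float


def _discretize(base: Dataset, n_bins: int) -> tuple[pd.DataFrame, dict[str, _Node]]:
    disc = pd.DataFrame(index=base.df.index)
    nodes: dict[str, _Node] = {}
    for v in base.schema.variables:
        col = base.df[v.name]
        if v.kind == "numeric":
            x = col.to_numpy(dtype=float)
            qs = np.linspace(0, 1, n_bins + 1)
            edges = np.unique(np.nanquantile(x, qs))
            if len(edges) < 2:
                edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
            codes = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
            disc[v.name] = codes
            nodes[v.name] = _Node(v.name, "numeric", sorted(np.unique(codes)), edges)
        else:
            disc[v.name] = col.to_numpy()
            nodes[v.name] = _Node(v.name, "categorical", sorted(col.unique()))
    return disc, nodes


def _family_loglik_and_dim(
    disc: pd.DataFrame, var: str, parents: tuple[str, ...], card: dict[str, int]
) -> tuple[float, int]:
    """Maximized log-likelihood and parameter count of one node family."""
    r = card[var]
    if parents:
        grouped = disc.groupby(list(parents), sort=False, observed=True)[var]
        ll = 0.0
        q = 0
        for _, sub in grouped:
            counts = sub.value_counts().to_numpy(dtype=float)
            n = counts.sum()
            ll += float((counts * np.log(counts / n)).sum())
            q += 1
        dim = q * (r - 1)
    else:
        counts = disc[var].value_counts().to_numpy(dtype=float)
        n = counts.sum()
        ll = float((counts * np.log(counts / n)).sum())
        dim = r - 1
    return ll, dim


def bic_score(disc: pd.DataFrame, dag: nx.DiGraph, card: dict[str, int]) -> float:
    """Decomposable BIC: sum of family log-likelihoods minus (log n / 2) * dim."""
    n = len(disc)
    total = 0.0
    for var in dag.nodes:
        parents = tuple(sorted(dag.predecessors(var)))
        ll, dim = _family_loglik_and_dim(disc, var, parents, card)
        total += ll - 0.5 * np.log(n) * dim
    return total


def hill_climb(
    disc: pd.DataFrame, variables: list[str], card: dict[str, int], max_parents: int = 3
) -> nx.DiGraph:
    """Greedy add/remove/reverse search maximizing BIC from an empty graph."""
    dag = nx.DiGraph()
    dag.add_nodes_from(variables)
    n = len(disc)
    log_n = np.log(n)

    def family_score(var: str, parents: tuple[str, ...]) -> float:
        ll, dim = _family_loglik_and_dim(disc, var, parents, card)
        return ll - 0.5 * log_n * dim

    fam: dict[str, float] = {
        v: family_score(v, ()) for v in variables
    }
    while True:
        best_delta, best_move = 1e-9, None
        for a, b in itertools.permutations(variables, 2):
            if dag.has_edge(a, b):
                # remove a->b
                parents = tuple(sorted(set(dag.predecessors(b)) - {a}))
                delta = family_score(b, parents) - fam[b]
                if delta > best_delta:
                    best_delta, best_move = delta, ("remove", a, b)
                # reverse a->b
                if dag.in_degree(a) < max_parents:
                    dag.remove_edge(a, b)
                    creates_cycle = nx.has_path(dag, a, b)
                    dag.add_edge(a, b)
                    if not creates_cycle:
                        pa = tuple(sorted(set(dag.predecessors(a)) | {b}))
                        pb = parents
                        delta = (
                            family_score(a, pa)
                            - fam[a]
                            + family_score(b, pb)
                            - fam[b]
                        )
                        if delta > best_delta:
                            best_delta, best_move = delta, ("reverse", a, b)
            elif not dag.has_edge(b, a):
                # add a->b
                if dag.in_degree(b) >= max_parents:
                    continue
                if nx.has_path(dag, b, a):
                    continue
                parents = tuple(sorted(set(dag.predecessors(b)) | {a}))
                delta = family_score(b, parents) - fam[b]
                if delta > best_delta:
                    best_delta, best_move = delta, ("add", a, b)
        if best_move is None:
            break
        op, a, b = best_move
        if op == "add":
            dag.add_edge(a, b)
        elif op == "remove":
            dag.remove_edge(a, b)
        else:
            dag.remove_edge(a, b)
            dag.add_edge(b, a)
            fam[a] = family_score(a, tuple(sorted(dag.predecessors(a))))
        fam[b] = family_score(b, tuple(sorted(dag.predecessors(b))))
    return dag


def _estimate_cpts(
    disc: pd.DataFrame,
    dag: nx.DiGraph,
    nodes: dict[str, _Node],
    prior_strength: float,
) -> dict[str, dict[tuple, np.ndarray]]:
    cpts: dict[str, dict[tuple, np.ndarray]] = {}
    for var in dag.nodes:
        levels = nodes[var].levels
        level_pos = {lv: i for i, lv in enumerate(levels)}
        parents = tuple(sorted(dag.predecessors(var)))
        table: dict[tuple, np.ndarray] = {}
        if parents:
            for key, sub in disc.groupby(list(parents), sort=False, observed=True)[var]:
                key = key if isinstance(key, tuple) else (key,)
                counts = np.full(len(levels), prior_strength)
                vc = sub.value_counts()
                for lv, c in vc.items():
                    counts[level_pos[lv]] += c
                table[key] = counts / counts.sum()
        else:
            counts = np.full(len(levels), prior_strength)
            vc = disc[var].value_counts()
            for lv, c in vc.items():
                counts[level_pos[lv]] += c
            table[()] = counts / counts.sum()
        cpts[var] = table
    return cpts


def fit_bayes_net_state(
    base: Dataset,
    max_parents: int = 3,
    prior_strength: float = 1.0,
    n_bins: int = 5,
) -> BayesNetState:
    if len(base.schema.variables) < 2:
        raise ValueError("Bayesian network requires at least 2 variables")
    if len(base) < 10:
        raise ValueError("base dataset too small to learn a Bayesian network")
    disc, nodes = _discretize(base, n_bins)
    variables = [v.name for v in base.schema.variables]
    card = {v: len(nodes[v].levels) for v in variables}
    dag = hill_climb(disc, variables, card, max_parents=max_parents)
    cpts = _estimate_cpts(disc, dag, nodes, prior_strength)
    order = list(nx.topological_sort(dag))
    return BayesNetState(dag=dag, nodes=nodes, cpts=cpts, order=order,
                         schema=base.schema, prior_strength=prior_strength)


def sample_bayes_net(state: BayesNetState, m: int, rng: np.random.Generator) -> pd.DataFrame:
    """Ancestral sampling in topological order; numerics drawn within bins."""
    disc_draws: dict[str, np.ndarray] = {}
    for var in state.order:
        node = state.nodes[var]
        levels = node.levels
        parents = tuple(sorted(state.dag.predecessors(var)))
        table = state.cpts[var]
        uniform = np.full(len(levels), 1.0 / len(levels))
        if parents:
            keys = list(zip(*(disc_draws[p] for p in parents)))
            probs = np.array([table.get(k, uniform) for k in keys])
        else:
            probs = np.tile(table[()], (m, 1))
        u = rng.random(m)
        cum = np.cumsum(probs, axis=1)
        idx = (u[:, None] > cum).sum(axis=1)
        disc_draws[var] = np.array(levels, dtype=object)[idx]

    out = pd.DataFrame(index=range(m))
    for v in state.schema.variables:
        node = state.nodes[v.name]
        draws = disc_draws[v.name]
        if node.kind == "numeric":
            bins = draws.astype(int)
            lo = node.bin_edges[bins]
            hi = node.bin_edges[bins + 1]
            out[v.name] = lo + rng.random(m) * (hi - lo)
        else:
            out[v.name] = draws
    return out[[v.name for v in state.schema.variables]]
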