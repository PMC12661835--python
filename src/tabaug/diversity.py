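"""Diversity of augmented data via extended-isolation-forest outlier scores.

A record added by augmentation counts as "diverse" to the extent that it is
an outlier relative to the base dataset.  An extended isolation forest —
isolation trees with random *oblique* hyperplane splits, which avoid the
axis-parallel branching bias of the classic isolation forest — is trained on
the base dataset; both the base and the augmented dataset are scored, each
score vector is summarized as a contamination curve (proportion of records
with score >= tau over the fixed grid tau = 0.01, 0.02, ..., 1.00), and the
diversity statistic is the mean over thresholds of the weighted positive
curve difference x(2 - x):

    diversity = (1/100) * sum_j [ 1(x_j >= 0) * x_j * (2 - x_j) ]

where x_j = augmented_rate_j - base_rate_j.  Negative differences contribute
nothing.  The statistic lives in [0, 1]: 0 when augmentation adds no
outlying structure, 1 when every augmented record outscores every threshold
the base does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Dataset

TAU_GRID = np.round(np.arange(1, 101) * 0.01, 2)
"""The fixed 100-threshold grid 0.01 .. 1.00."""


# ---------------------------------------------------------------------------
# Mixed-type encoding (outcome-free, so outcome labels cannot leak into the
# diversity measurement)


@dataclass
class _FrequencyEncoder:
    """Min-max scaled numerics + level-frequency encoded categoricals."""

    mins: dict[str, float] = field(default_factory=dict)
    ranges: dict[str, float] = field(default_factory=dict)
    freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    schema: object = None

    def fit(self, base: Dataset) -> "_FrequencyEncoder":
        self.schema = base.schema
        for v in base.schema.predictors:
            col = base.df[v.name]
            if v.kind == "numeric":
                x = col.to_numpy(dtype=float)
                lo = float(np.nanmin(x)) if np.isfinite(np.nanmin(x)) else 0.0
                hi = float(np.nanmax(x)) if np.isfinite(np.nanmax(x)) else 1.0
                self.mins[v.name] = lo
                self.ranges[v.name] = max(hi - lo, 1e-12)
            else:
                self.freqs[v.name] = col.value_counts(normalize=True).to_dict()
        return self

    def transform(self, ds: Dataset) -> np.ndarray:
        cols = []
        for v in self.schema.predictors:
            col = ds.df[v.name]
            if v.kind == "numeric":
                x = col.to_numpy(dtype=float)
                x = (x - self.mins[v.name]) / self.ranges[v.name]
                cols.append(np.nan_to_num(x, nan=0.5))
            else:
                f = self.freqs[v.name]
                cols.append(col.map(lambda lv: f.get(lv, 0.0)).to_numpy(dtype=float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Extended isolation forest


def _harmonic(i: float) -> float:
    return np.log(i) + np.euler_gamma


def average_path_length(psi: int | np.ndarray) -> np.ndarray:
    """c(psi): expected unsuccessful-search path length in a BST of size psi."""
    psi = np.asarray(psi, dtype=float)
    out = np.zeros_like(psi)
    big = psi > 2
    out[big] = 2.0 * _harmonic(psi[big] - 1.0) - 2.0 * (psi[big] - 1.0) / psi[big]
    out[psi == 2] = 1.0
    return out


@dataclass
class _TreeNode:
    size: int
    normal: np.ndarray | None = None
    intercept: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None


def _grow_tree(X: np.ndarray, depth: int, limit: int, rng: np.random.Generator) -> _TreeNode:
    n = len(X)
    if n <= 1 or depth >= limit:
        return _TreeNode(size=n)
    normal = rng.standard_normal(X.shape[1])
    proj = X @ normal
    lo, hi = proj.min(), proj.max()
    if hi <= lo:
        return _TreeNode(size=n)
    intercept = rng.uniform(lo, hi)
    mask = proj < intercept
    if mask.all() or not mask.any():
        return _TreeNode(size=n)
    return _TreeNode(
        size=n,
        normal=normal,
        intercept=intercept,
        left=_grow_tree(X[mask], depth + 1, limit, rng),
        right=_grow_tree(X[~mask], depth + 1, limit, rng),
    )


def _path_lengths(node: _TreeNode, X: np.ndarray, depth: float, out: np.ndarray, idx: np.ndarray) -> None:
    if node.normal is None:
        out[idx] = depth + average_path_length(np.array([node.size]))[0]
        return
    proj = X @ node.normal
    mask = proj < node.intercept
    if mask.any():
        _path_lengths(node.left, X[mask], depth + 1, out, idx[mask])
    if (~mask).any():
        _path_lengths(node.right, X[~mask], depth + 1, out, idx[~mask])


@dataclass
class EIFModel:
    """Extended isolation forest fitted on a base dataset.

    Oblique splits use a fully random hyperplane (standard-normal vector
    over all encoded dimensions, intercept uniform within the node's
    projection range); each tree is grown on a psi-subsample to the depth
    limit ceil(log2 psi).  Anomaly scores use the classic normalization
    s = 2^(-E[h]/c(psi)), so they live in (0, 1) and the fixed tau grid is
    meaningful.
    """

    trees: list[_TreeNode]
    subsample_size: int
    encoder: _FrequencyEncoder

    def score(self, ds: Dataset) -> np.ndarray:
        X = self.encoder.transform(ds)
        paths = np.zeros((len(self.trees), len(X)))
        idx = np.arange(len(X))
        for t, tree in enumerate(self.trees):
            _path_lengths(tree, X, 0.0, paths[t], idx)
        mean_path = paths.mean(axis=0)
        c = average_path_length(np.array([self.subsample_size]))[0]
        return np.power(2.0, -mean_path / max(c, 1e-12))


def fit_eif(
    base: Dataset, n_trees: int = 200, subsample: int | None = None, seed: int = 0
) -> EIFModel:
    """Fit the forest on the base dataset (predictors only)."""
    if len(base) < 2:
        raise ValueError("need at least 2 rows to fit an isolation forest")
    psi = subsample if subsample is not None else min(256, len(base))
    if psi > len(base):
        raise ValueError("subsample size exceeds the base dataset size")
    encoder = _FrequencyEncoder().fit(base)
    X = encoder.transform(base)
    rng = np.random.default_rng(seed)
    limit = int(np.ceil(np.log2(max(psi, 2))))
    trees = []
    for _ in range(n_trees):
        sub = X[rng.choice(len(X), size=psi, replace=False)]
        trees.append(_grow_tree(sub, 0, limit, rng))
    return EIFModel(trees=trees, subsample_size=psi, encoder=encoder)


# ---------------------------------------------------------------------------
# Contamination curves and the diversity statistic


@dataclass
class ContaminationCurve:
    thresholds: np.ndarray
    rates: np.ndarray


@dataclass
class DiversityResult:
    x: np.ndarray  # per-threshold rate difference, augmented - base
    diversity: float


def contamination_curve(scores: np.ndarray) -> ContaminationCurve:
    """Proportion of records with score >= tau over the fixed grid."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    rates = (scores[None, :] >= TAU_GRID[:, None]).mean(axis=1)
    return ContaminationCurve(thresholds=TAU_GRID.copy(), rates=rates)


def diversity(base_curve: ContaminationCurve, aug_curve: ContaminationCurve) -> DiversityResult:
    """Mean weighted positive contamination-curve difference."""
    if not np.array_equal(base_curve.thresholds, aug_curve.thresholds):
        raise ValueError("threshold grids differ")
    x = aug_curve.rates - base_curve.rates
    terms = np.where(x >= 0, x * (2.0 - x), 0.0)
    return DiversityResult(x=x, diversity=float(terms.mean()))


def dataset_diversity(
    base: Dataset,
    augmented: Dataset,
    n_trees: int = 200,
    subsample: int | None = None,
    seed: int = 0,
) -> DiversityResult:
    """Fit the forest on ``base`` only, score both datasets, compare curves."""
    if augmented.schema != base.schema:
        raise ValueError("base and augmented datasets must share a schema")
    model = fit_eif(base, n_trees=n_trees, subsample=subsample, seed=seed)
    base_curve = contamination_curve(model.score(base))
    aug_curve = contamination_curve(model.score(augmented))
    return diversity(base_curve, aug_curve)
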