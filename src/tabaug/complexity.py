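"""The eight dataset characteristics fed to the augmentation-benefit model.

A dataset's propensity to benefit from augmentation is modelled from: its
base size n0, total predictor degrees of freedom, outcome imbalance factor,
mean standardized entropy of the predictors, the coefficient of variation of
pairwise predictor mutual information, a Gower-distance class-separability
ratio, the baseline workload ROC-AUC, and the number of predictors.
Numerics are discretized into equal-frequency bins (default 10) for the
entropy and mutual-information estimates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import entropy as shannon_entropy
from sklearn.metrics import mutual_info_score

from .core import Dataset, Schema
from .workload import WorkloadSettings, evaluate_auc, train_workload


@dataclass
class ComplexityProfile:
    n0: int
    degrees_of_freedom: int
    imbalance_factor: float
    std_entropy: float
    mi_cv: float
    separability: float
    baseline_auc: float
    n_predictors: int

    def to_dict(self) -> dict:
        return asdict(self)


def imbalance_factor(outcome01: np.ndarray) -> float:
    """max(p/(1-p), (1-p)/p) of outcome prevalence p; 1 means balanced."""
    y = np.asarray(outcome01)
    p = float(y.mean())
    if p <= 0.0 or p >= 1.0:
        raise ValueError("both outcome classes must be present")
    return max(p / (1 - p), (1 - p) / p)


def degrees_of_freedom(schema: Schema) -> int:
    """1 per numeric predictor, k-1 per k-level categorical predictor."""
    total = 0
    for v in schema.predictors:
        total += 1 if v.kind == "numeric" else len(v.levels) - 1
    return total


def _discretize_column(ds: Dataset, name: str, n_bins: int) -> np.ndarray:
    v = ds.schema[name]
    col = ds.df[name]
    if v.kind == "categorical":
        return col.to_numpy()
    x = col.to_numpy(dtype=float)
    ok = ~np.isnan(x)
    edges = np.unique(np.nanquantile(x[ok], np.linspace(0, 1, n_bins + 1))) if ok.any() else np.array([0.0, 1.0])
    if len(edges) < 2:
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    codes = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    out = codes.astype(object)
    out[~ok] = "__nan__"
    return out


def standardized_entropy(data: Dataset, n_bins: int = 10) -> float:
    """Mean over predictors of Shannon entropy normalized by log(k).

    A predictor with a single observed level contributes 0 (H / log 1 is
    defined as 0).
    """
    values = []
    for v in data.schema.predictors:
        codes = _discretize_column(data, v.name, n_bins)
        counts = pd.Series(codes).value_counts().to_numpy(dtype=float)
        k = len(counts)
        if k < 2:
            values.append(0.0)
            continue
        values.append(float(shannon_entropy(counts / counts.sum()) / np.log(k)))
    if not values:
        raise ValueError("at least one predictor is required")
    return float(np.mean(values))


def mutual_info_cv(data: Dataset, n_bins: int = 10) -> float:
    """Coefficient of variation (sample SD / mean) of pairwise predictor MI.

    Plug-in MI on the discretized contingency table, natural log.  Returns 0
    with a warning when the mean MI is 0.
    """
    preds = data.schema.predictors
    if len(preds) < 2:
        raise ValueError("mutual_info_cv requires at least 2 predictors")
    cols = {v.name: _discretize_column(data, v.name, n_bins) for v in preds}
    mis = [
        mutual_info_score(cols[a.name], cols[b.name])
        for a, b in itertools.combinations(preds, 2)
    ]
    mis = np.asarray(mis, dtype=float)
    mean = mis.mean()
    if mean == 0.0:
        warnings.warn("all pairwise mutual information is zero; CV set to 0")
        return 0.0
    sd = mis.std(ddof=1) if len(mis) > 1 else 0.0
    return float(sd / mean)


# ---------------------------------------------------------------------------
# Gower distance and separability


def _gower_matrix(data: Dataset) -> np.ndarray:
    """Pairwise Gower distances between all rows (predictors only).

    Numeric contributions are |a-b|/range (0 when the range is 0, skipped
    when either value is missing); categorical contributions are 0/1
    mismatch.  The distance is the mean of the available contributions.
    """
    n = len(data)
    total = np.zeros((n, n))
    weight = np.zeros((n, n))
    for v in data.schema.predictors:
        if v.kind == "numeric":
            x = data.df[v.name].to_numpy(dtype=float)
            ok = ~np.isnan(x)
            rng = np.nanmax(x) - np.nanmin(x) if ok.any() else 0.0
            avail = np.outer(ok, ok)
            if rng > 0:
                diff = np.abs(x[:, None] - x[None, :]) / rng
                total += np.where(avail, np.nan_to_num(diff), 0.0)
            weight += avail
        else:
            codes = pd.Categorical(data.df[v.name]).codes
            total += (codes[:, None] != codes[None, :]).astype(float)
            weight += 1.0
    with np.errstate(invalid="ignore"):
        d = np.where(weight > 0, total / np.maximum(weight, 1), 0.0)
    return d


def gower_distance(a: pd.Series, b: pd.Series, schema: Schema, ranges: dict[str, float]) -> float:
    """Gower distance between two records given per-numeric observed ranges."""
    contribs = []
    for v in schema.predictors:
        if v.kind == "numeric":
            av, bv = float(a[v.name]), float(b[v.name])
            if np.isnan(av) or np.isnan(bv):
                continue
            rng = ranges.get(v.name, 0.0)
            contribs.append(abs(av - bv) / rng if rng > 0 else 0.0)
        else:
            contribs.append(0.0 if a[v.name] == b[v.name] else 1.0)
    if not contribs:
        return 0.0
    return float(np.mean(contribs))


def separability(
    data: Dataset,
    aggregation: str = "ratio_of_means",
    max_rows: int = 2000,
    seed: int = 0,
) -> float:
    """Intraclass / interclass nearest-neighbour Gower distance ratio.

    For each record, the distance to its nearest same-class neighbour
    (excluding itself) and to its nearest other-class neighbour are found by
    brute force on the Gower matrix; the statistic is mean(d_intra) /
    mean(d_inter) (or the mean of per-record ratios when ``aggregation`` is
    ``"mean_of_ratios"``).  Lower values mean better-separated classes.
    Datasets larger than ``max_rows`` are subsampled (stratified, seeded) to
    keep the O(n^2) distance matrix tractable.
    """
    y = data.outcome01()
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("both classes need >=2 rows for separability")
    if len(data) > max_rows:
        rng = np.random.default_rng(seed)
        keep = []
        for cls in (0, 1):
            members = np.flatnonzero(y == cls)
            take = max(2, int(round(max_rows * len(members) / len(y))))
            keep.append(rng.choice(members, size=min(take, len(members)), replace=False))
        data = data.subset(np.sort(np.concatenate(keep)))
        y = data.outcome01()
    d = _gower_matrix(data)
    np.fill_diagonal(d, np.inf)
    same = y[:, None] == y[None, :]
    d_intra = np.where(same, d, np.inf).min(axis=1)
    d_inter = np.where(~same, d, np.inf).min(axis=1)
    if aggregation == "ratio_of_means":
        denom = float(d_inter.mean())
        if denom == 0.0:
            raise ValueError("mean interclass NN distance is 0 (duplicate-dominated data)")
        return float(d_intra.mean()) / denom
    elif aggregation == "mean_of_ratios":
        ok = d_inter > 0
        if not ok.any():
            raise ValueError("all interclass NN distances are 0")
        return float(np.mean(d_intra[ok] / d_inter[ok]))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def profile(
    base: Dataset,
    test: Dataset | None = None,
    workload_settings: WorkloadSettings | None = None,
    n_bins: int = 10,
    baseline_auc: float | None = None,
) -> ComplexityProfile:
    """Assemble all eight characteristics for a base dataset.

    ``baseline_auc`` is the workload trained on the un-augmented base and
    evaluated on ``test``; it may instead be supplied directly (as when the
    caller has already averaged it over CV folds).
    """
    if baseline_auc is None:
        if test is None:
            raise ValueError("either a test set or a precomputed baseline_auc is required")
        fitted = train_workload(base, workload_settings)
        baseline_auc = evaluate_auc(fitted, test)
    return ComplexityProfile(
        n0=len(base),
        degrees_of_freedom=degrees_of_freedom(base.schema),
        imbalance_factor=imbalance_factor(base.outcome01()),
        std_entropy=standardized_entropy(base, n_bins),
        mi_cv=mutual_info_cv(base, n_bins),
        separability=separability(base),
        baseline_auc=float(baseline_auc),
        n_predictors=len(base.schema.predictors),
    )
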