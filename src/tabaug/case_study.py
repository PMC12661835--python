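"""Nested cross-validated augmentation evaluation (part-2 engine).

For a small clinical dataset: a stratified 5-fold outer loop in which every
generator is fitted on the training partition only (no leakage into the
evaluation fold), augmented training sets over a ladder of synthetic sizes
n' are scored on the held-out fold, and fold-averaged ROC-AUC selects the
best (generator, n'_max) pair.  A bootstrap rerun at exactly n'_max serves
as the "more rows, no new diversity" control, and exact sign-flip
permutation tests compare paired results across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import Dataset
from .diversity import dataset_diversity
from .generators import augment, fit_generator
from .grid import round_half_away
from .workload import WorkloadSettings, evaluate_auc, train_workload

DEFAULT_N_PRIME_GRID: tuple[int, ...] = tuple(
    round_half_away(1.5 ** (i + 4)) for i in range(1, 31)
)
"""Geometric ladder [1.5^(i+4)], i = 1..30 (8 .. ~970,000 synthetic rows)."""


@dataclass
class CaseStudyResult:
    dataset_id: str
    best_generator: str
    n_prime_max: int
    baseline_auc: float
    augmented_auc: float
    relative_improvement: float
    resampled_auc: float | None = None
    diversity_generative: float | None = None
    diversity_resample: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PairedTestResult:
    observed_mean_difference: float
    p_value: float
    n_pairs: int
    n_enumerated: int
    n_extreme: int
    exact: bool


def relative_improvement(baseline: float, augmented: float) -> float:
    """(augmented - baseline) / baseline x 100, in percent."""
    if baseline <= 0:
        raise ValueError("baseline ROC-AUC must be positive")
    return (augmented - baseline) / baseline * 100.0


def exact_paired_permutation_test(
    differences: np.ndarray | list[float],
    n_resamples: int = 100_000,
    seed: int = 0,
) -> PairedTestResult:
    """One-tailed exact sign-flip test for the mean paired difference.

    All 2^n sign assignments of |d_i| are enumerated (n <= 20) and the
    p-value is the proportion whose mean is >= the observed mean, ties
    counting as extreme.  Larger n falls back to Monte-Carlo sign flips with
    the resampling count reported.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 1:
        raise ValueError("need at least one paired difference")
    observed = d.sum()
    absd = np.abs(d)
    if n <= 20:
        count = 0
        n_total = 2**n
        chunk = 1 << min(n, 16)
        masks = np.arange(chunk, dtype=np.uint32)
        bits_low = ((masks[:, None] >> np.arange(min(n, 16))) & 1).astype(np.int8)
        for hi in range(n_total // chunk):
            if n > 16:
                hi_bits = np.array([(hi >> k) & 1 for k in range(n - 16)], dtype=np.int8)
                signs = np.concatenate(
                    [bits_low, np.tile(hi_bits, (chunk, 1))], axis=1
                ) * 2 - 1
            else:
                signs = bits_low * 2 - 1
            sums = signs @ absd
            count += int((sums >= observed - 1e-12).sum())
        return PairedTestResult(
            observed_mean_difference=float(d.mean()),
            p_value=count / n_total,
            n_pairs=n,
            n_enumerated=n_total,
            n_extreme=count,
            exact=True,
        )
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_resamples, n)) * 2 - 1
    sums = signs @ absd
    count = int((sums >= observed - 1e-12).sum())
    return PairedTestResult(
        observed_mean_difference=float(d.mean()),
        p_value=count / n_resamples,
        n_pairs=n,
        n_enumerated=n_resamples,
        n_extreme=count,
        exact=False,
    )


def _outer_folds(data: Dataset, n_folds: int, seed: int):
    y = data.outcome01()
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def nested_cv_evaluate(
    data: Dataset,
    generators: tuple[str, ...] = ("bootstrap", "seq_trees", "bayes_net"),
    n_prime_grid: tuple[int, ...] = DEFAULT_N_PRIME_GRID,
    settings: WorkloadSettings | None = None,
    n_folds: int = 5,
    seed: int = 0,
    compute_diversity: bool = True,
    eif_trees: int = 200,
) -> CaseStudyResult:
    """Stratified nested CV selection of the best (generator, n').

    The baseline ROC-AUC is the fold average of the workload trained on each
    un-augmented training partition; the final AUC per (generator, n') is
    the fold average of the augmented workloads; the maximizing pair wins,
    with the smallest n' breaking ties.  Diversity of the winning augmented
    data (and of the bootstrap control at the same n'_max, via
    :func:`resampling_comparison`) is fold-averaged as well.
    """
    settings = settings or WorkloadSettings()
    folds = _outer_folds(data, n_folds, seed)
    rng = np.random.default_rng(seed)

    baseline_aucs = []
    auc_by_cell: dict[tuple[str, int], list[float]] = {
        (g, np_): [] for g in generators for np_ in n_prime_grid
    }
    fold_models: list[dict[str, object]] = []
    fold_sets: list[tuple[Dataset, Dataset]] = []
    for tr_idx, te_idx in folds:
        tr = data.subset(tr_idx, id=f"{data.id}:fold-train")
        te = data.subset(te_idx, id=f"{data.id}:fold-test")
        fold_sets.append((tr, te))
        baseline_aucs.append(evaluate_auc(train_workload(tr, settings), te))
        models = {
            g: fit_generator(g, tr, seed=int(rng.integers(2**31))) for g in generators
        }
        fold_models.append(models)
        for g in generators:
            for n_prime in n_prime_grid:
                aug = augment(tr, models[g], n_prime, seed=int(rng.integers(2**31)))
                try:
                    auc = evaluate_auc(train_workload(aug, settings), te)
                except ValueError:
                    auc = np.nan
                auc_by_cell[(g, n_prime)].append(auc)

    baseline_auc = float(np.mean(baseline_aucs))
    mean_auc = {
        cell: float(np.nanmean(v)) if not np.all(np.isnan(v)) else -np.inf
        for cell, v in auc_by_cell.items()
    }
    # max mean AUC; ties -> smallest n', then generator order
    best_cell = max(
        mean_auc,
        key=lambda c: (mean_auc[c], -c[1], -generators.index(c[0])),
    )
    best_gen, n_prime_max = best_cell
    augmented_auc = mean_auc[best_cell]

    div_gen = None
    if compute_diversity:
        divs = []
        for (tr, _), models in zip(fold_sets, fold_models):
            aug = augment(tr, models[best_gen], n_prime_max, seed=int(rng.integers(2**31)))
            divs.append(
                dataset_diversity(
                    tr, aug, n_trees=eif_trees, seed=int(rng.integers(2**31))
                ).diversity
            )
        div_gen = float(np.mean(divs))

    return CaseStudyResult(
        dataset_id=data.id,
        best_generator=best_gen,
        n_prime_max=int(n_prime_max),
        baseline_auc=baseline_auc,
        augmented_auc=augmented_auc,
        relative_improvement=relative_improvement(baseline_auc, augmented_auc),
        diversity_generative=div_gen,
    )


def resampling_comparison(
    data: Dataset,
    n_prime_max: int,
    settings: WorkloadSettings | None = None,
    n_folds: int = 5,
    seed: int = 0,
    compute_diversity: bool = True,
    eif_trees: int = 200,
) -> tuple[float, float | None]:
    """Bootstrap control: the nested CV rerun at exactly n' = n_prime_max.

    Returns the fold-averaged ROC-AUC of bootstrap-augmented training and,
    optionally, the fold-averaged diversity of the resampled data.
    """
    settings = settings or WorkloadSettings()
    folds = _outer_folds(data, n_folds, seed)
    rng = np.random.default_rng(seed)
    aucs, divs = [], []
    for tr_idx, te_idx in folds:
        tr = data.subset(tr_idx)
        te = data.subset(te_idx)
        model = fit_generator("bootstrap", tr, seed=int(rng.integers(2**31)))
        aug = augment(tr, model, n_prime_max, seed=int(rng.integers(2**31)))
        assert len(aug) == len(tr) + n_prime_max
        aucs.append(evaluate_auc(train_workload(aug, settings), te))
        if compute_diversity:
            divs.append(
                dataset_diversity(
                    tr, aug, n_trees=eif_trees, seed=int(rng.integers(2**31))
                ).diversity
            )
    return float(np.mean(aucs)), (float(np.mean(divs)) if compute_diversity else None)


def run_case_study(
    data: Dataset,
    generators: tuple[str, ...] = ("bootstrap", "seq_trees", "bayes_net"),
    n_prime_grid: tuple[int, ...] = DEFAULT_N_PRIME_GRID,
    settings: WorkloadSettings | None = None,
    n_folds: int = 5,
    seed: int = 0,
    eif_trees: int = 200,
) -> CaseStudyResult:
    """Full per-dataset case study: selection plus the bootstrap control."""
    result = nested_cv_evaluate(
        data, generators, n_prime_grid, settings, n_folds, seed, eif_trees=eif_trees
    )
    resampled_auc, div_resample = resampling_comparison(
        data, result.n_prime_max, settings, n_folds, seed, eif_trees=eif_trees
    )
    result.resampled_auc = resampled_auc
    result.diversity_resample = div_resample
    return result
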