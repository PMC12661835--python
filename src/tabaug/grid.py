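"""Population-scale augmentation grid (part-1 engine).

From one population: a single stratified 70/30 train/test split; for each
base size n0, a stratified base sample and its baseline ROC-AUC on the fixed
test set; for each generator, 10 geometric series of 30 synthetic-data sizes
n' = [b^(i+4)] with b ~ N(1.5, 0.005) drawn once per series; one workload
training + test-set evaluation per augmented dataset.  The full design is
40 n0 values x 10 series x 30 sizes = 12,000 augmented datasets per
generator per population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import Dataset, split_population, stratified_sample
from .generators import augment, fit_generator
from .workload import WorkloadSettings, evaluate_auc, train_workload

logger = logging.getLogger(__name__)

DEFAULT_N0_VALUES: tuple[int, ...] = tuple(
    list(range(20, 101, 10))
    + list(range(150, 1001, 50))
    + list(range(2000, 10_001, 1000))
    + list(range(20_000, 50_001, 10_000))
)
"""The 40 base-dataset sizes of the full design (20 .. 50,000)."""


def round_half_away(x: float) -> int:
    """[x]: round to the closest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def derive_seed(*parts: int | str) -> int:
    """Deterministic sub-seed from a tuple of ints/strings (< 2^31)."""
    import zlib

    entropy = [
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts
    ]
    return int(np.random.default_rng(entropy).integers(2**31))


@dataclass
class GridConfig:
    n0_values: tuple[int, ...] = DEFAULT_N0_VALUES
    n_series: int = 10
    series_length: int = 30
    b_mean: float = 1.5
    b_sd: float = 0.005
    generators: tuple[str, ...] = ("bootstrap", "seq_trees", "bayes_net")
    train_fraction: float = 0.7
    b_per_element: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.n0_values) != sorted(set(self.n0_values)):
            raise ValueError("n0_values must be strictly increasing")
        if self.series_length < 1:
            raise ValueError("series_length must be >= 1")

    @property
    def cells_per_generator(self) -> int:
        return len(self.n0_values) * self.n_series * self.series_length

    @property
    def cells_per_n0(self) -> int:
        return self.n_series * self.series_length


@dataclass
class SimulationRecord:
    dataset_id: str
    generator: str
    n0: int
    n_prime: int
    series_id: int
    auc: float
    baseline_auc: float
    failed: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def geometric_series(config: GridConfig, series_seed: int) -> list[int]:
    """One series of ``series_length`` synthetic-data sizes.

    A single growth factor b is drawn from N(b_mean, b_sd) per series
    (resampled in the negligible event b <= 1); element i is
    [b^(i+4)] for i = 1..series_length.  With ``b_per_element`` a fresh b is
    drawn for every element.
    """
    rng = np.random.default_rng(series_seed)

    def draw_b() -> float:
        for _ in range(100):
            b = rng.normal(config.b_mean, config.b_sd)
            if b > 1.0:
                return b
        raise RuntimeError("could not draw a growth factor b > 1")

    if config.b_per_element:
        return [round_half_away(draw_b() ** (i + 4)) for i in range(1, config.series_length + 1)]
    b = draw_b()
    return [round_half_away(b ** (i + 4)) for i in range(1, config.series_length + 1)]


def draw_base(train: Dataset, n0: int, seed: int) -> Dataset:
    """Outcome-stratified sample of n0 training rows without replacement."""
    if n0 > len(train):
        raise ValueError(f"n0={n0} exceeds the training set size {len(train)}")
    if n0 < 2:
        raise ValueError("n0 must allow both outcome classes")
    return stratified_sample(train, n0, seed=seed, replace=False)


def run_grid(
    population: Dataset,
    config: GridConfig | None = None,
    workload_settings: WorkloadSettings | None = None,
) -> list[SimulationRecord]:
    """Run the full n0 x generator x series x n' grid on one population.

    The 70/30 split happens once; the same test partition evaluates every
    cell.  Generators are fitted on the base sample only.  Cells whose
    augmented data degenerate (e.g. a single outcome class) are recorded
    with ``failed=True`` rather than dropped.
    """
    config = config or GridConfig()
    settings = workload_settings or WorkloadSettings()
    rng = np.random.default_rng(config.seed)
    pair = split_population(
        population, config.train_fraction, seed=derive_seed(config.seed, "split")
    )
    train, test = pair.train, pair.test

    records: list[SimulationRecord] = []
    for n0 in config.n0_values:
        # base seed derivable from (config seed, n0) so callers can rebuild
        # the exact base sample a record's baseline came from
        base = draw_base(train, n0, seed=derive_seed(config.seed, "base", n0))
        baseline_model = train_workload(base, settings)
        baseline_auc = evaluate_auc(baseline_model, test)
        for gen_name in config.generators:
            model = fit_generator(gen_name, base, seed=int(rng.integers(2**31)))
            for series_id in range(config.n_series):
                sizes = geometric_series(config, series_seed=int(rng.integers(2**31)))
                for n_prime in sizes:
                    cell_seed = int(rng.integers(2**31))
                    try:
                        aug = augment(base, model, n_prime, seed=cell_seed)
                        fitted = train_workload(aug, settings)
                        auc = evaluate_auc(fitted, test)
                        failed = False
                    except ValueError as e:
                        logger.warning(
                            "cell failed (%s n0=%d n'=%d series=%d): %s",
                            gen_name, n0, n_prime, series_id, e,
                        )
                        auc, failed = float("nan"), True
                    records.append(
                        SimulationRecord(
                            dataset_id=population.id,
                            generator=gen_name,
                            n0=n0,
                            n_prime=n_prime,
                            series_id=series_id,
                            auc=auc,
                            baseline_auc=baseline_auc,
                            failed=failed,
                        )
                    )
    return records
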