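import numpy as np
import pandas as pd
import pytest

from tabaug.core import Dataset, Schema, VariableSpec
from tabaug.synthpop import generate_population, preset_population
from tabaug.workload import FAST_SETTINGS


@pytest.fixture
def tiny_schema() -> Schema:
    return Schema(
        (
            VariableSpec("age", "numeric"),
            VariableSpec("sex", "categorical", ("M", "F")),
            VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
        )
    )


def make_tiny(tiny_schema: Schema, rows: list[tuple]) -> Dataset:
    df = pd.DataFrame(rows, columns=["age", "sex", "outcome"])
    return Dataset(tiny_schema, df, id="tiny")


@pytest.fixture(scope="session")
def simple_pop() -> Dataset:
    return generate_population(preset_population("simple", n_rows=8000, seed=1))


@pytest.fixture(scope="session")
def complex_pop() -> Dataset:
    return generate_population(preset_population("complex", n_rows=20_000, seed=7))


@pytest.fixture(scope="session")
def fast_settings():
    return FAST_SETTINGS


def random_mixed_dataset(seed: int, n: int = 200) -> Dataset:
    """Small seeded mixed-type dataset for property tests."""
    rng = np.random.default_rng(seed)
    schema = Schema(
        (
            VariableSpec("x1", "numeric"),
            VariableSpec("x2", "numeric"),
            VariableSpec("c1", "categorical", ("a", "b", "c")),
            VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
        )
    )
    df = pd.DataFrame(
        {
            "x1": rng.standard_normal(n),
            "x2": rng.standard_normal(n),
            "c1": rng.choice(["a", "b", "c"], size=n),
            "outcome": rng.choice(["0", "1"], size=n).astype(object),
        }
    )
    return Dataset(schema, df, id=f"rand{seed}")
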