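"""The eight dataset characteristics: hand values, invariances, separability."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_mixed_dataset
from tabaug.complexity import (
    degrees_of_freedom,
    gower_distance,
    imbalance_factor,
    mutual_info_cv,
    profile,
    separability,
    standardized_entropy,
)
from tabaug.core import Dataset, Schema, VariableSpec


def one_numeric_dataset(values, labels) -> Dataset:
    schema = Schema(
        (
            VariableSpec("x", "numeric"),
            VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
        )
    )
    return Dataset(
        schema, pd.DataFrame({"x": values, "outcome": [str(l) for l in labels]})
    )


class TestImbalanceFactor:
    @pytest.mark.parametrize(
        "prevalence,expected",
        [(0.5, 1.0), (0.2, 4.0), (0.8, 4.0)],
    )
    def test_hand_values(self, prevalence, expected):
        n = 1000
        y = np.zeros(n)
        y[: int(n * prevalence)] = 1
        assert imbalance_factor(y) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            imbalance_factor(np.ones(10))


class TestDegreesOfFreedom:
    def test_summation(self):
        schema = Schema(
            (
                VariableSpec("a", "numeric"),
                VariableSpec("b", "numeric"),
                VariableSpec("c", "categorical", ("x", "y", "z")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        assert degrees_of_freedom(schema) == 1 + 1 + 2

    def test_numeric_counts_one_categorical_k_minus_one(self):
        schema = Schema(
            (
                VariableSpec("n", "numeric"),
                VariableSpec("k5", "categorical", tuple("abcde")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        assert degrees_of_freedom(schema) == 1 + 4


class TestStandardizedEntropy:
    def test_uniform_categorical_is_one(self):
        rng = np.random.default_rng(1)
        schema = Schema(
            (
                VariableSpec("c", "categorical", ("a", "b", "c", "d")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        df = pd.DataFrame(
            {
                "c": np.repeat(["a", "b", "c", "d"], 250),
                "outcome": rng.choice(["0", "1"], 1000),
            }
        )
        assert standardized_entropy(Dataset(schema, df)) == pytest.approx(1.0)

    def test_constant_variable_contributes_zero(self):
        ds = one_numeric_dataset([5.0] * 20, [0, 1] * 10)
        assert standardized_entropy(ds) == 0.0

    def test_binary_hand_value(self):
        # H(0.25) / ln 2 = (-0.25 ln 0.25 - 0.75 ln 0.75) / ln 2
        schema = Schema(
            (
                VariableSpec("c", "categorical", ("a", "b")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        df = pd.DataFrame(
            {"c": ["a"] * 25 + ["b"] * 75, "outcome": ["0", "1"] * 50}
        )
        expected = (-0.25 * np.log(0.25) - 0.75 * np.log(0.75)) / np.log(2)
        assert standardized_entropy(Dataset(schema, df)) == pytest.approx(expected)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_invariant_to_level_relabeling(self):
        ds = random_mixed_dataset(21, n=300)
        relabeled = ds.df.copy()
        relabeled["c1"] = relabeled["c1"].map({"a": "zz", "b": "yy", "c": "xx"})
        schema2 = Schema(
            tuple(
                VariableSpec(v.name, v.kind, ("xx", "yy", "zz") if v.name == "c1" else v.levels, v.role)
                for v in ds.schema.variables
            )
        )
        ds2 = Dataset(schema2, relabeled)
        assert standardized_entropy(ds2) == pytest.approx(standardized_entropy(ds))


class TestMutualInfoCV:
    def test_hand_value_from_two_pairs(self):
        # CV of {0.1, 0.3} with sample SD: sd = 0.1414, mean = 0.2
        mis = np.array([0.1, 0.3])
        assert mis.std(ddof=1) / mis.mean() == pytest.approx(np.sqrt(2) / 2, abs=1e-4)

    def test_identical_pairwise_mi_gives_zero(self):
        # 2 predictors -> a single pair -> zero dispersion
        rng = np.random.default_rng(2)
        schema = Schema(
            (
                VariableSpec("a", "categorical", ("0", "1")),
                VariableSpec("b", "categorical", ("0", "1")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        a = rng.choice(["0", "1"], 500)
        df = pd.DataFrame({"a": a, "b": a, "outcome": rng.choice(["0", "1"], 500)})
        assert mutual_info_cv(Dataset(schema, df)) == 0.0

    def test_single_predictor_rejected(self):
        ds = one_numeric_dataset([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        with pytest.raises(ValueError):
            mutual_info_cv(ds)

    def test_zero_mean_mi_warns_and_returns_zero(self):
        schema = Schema(
            (
                VariableSpec("a", "categorical", ("0", "1")),
                VariableSpec("b", "categorical", ("0", "1")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        # perfectly balanced independent 2x2 -> plug-in MI exactly 0
        df = pd.DataFrame(
            {
                "a": ["0", "0", "1", "1"] * 25,
                "b": ["0", "1", "0", "1"] * 25,
                "outcome": ["0", "1"] * 50,
            }
        )
        with pytest.warns(UserWarning):
            assert mutual_info_cv(Dataset(schema, df)) == 0.0


class TestGowerDistance:
    def make(self):
        schema = Schema(
            (
                VariableSpec("x", "numeric"),
                VariableSpec("c", "categorical", ("a", "b")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        return schema

    def test_identical_records_zero(self):
        schema = self.make()
        a = pd.Series({"x": 5.0, "c": "a"})
        assert gower_distance(a, a, schema, {"x": 10.0}) == 0.0

    def test_all_categorical_mismatch_one(self):
        schema = Schema(
            (
                VariableSpec("c1", "categorical", ("a", "b")),
                VariableSpec("c2", "categorical", ("a", "b")),
                VariableSpec("outcome", "categorical", ("0", "1"), role="outcome"),
            )
        )
        a = pd.Series({"c1": "a", "c2": "a"})
        b = pd.Series({"c1": "b", "c2": "b"})
        assert gower_distance(a, b, schema, {}) == 1.0

    def test_mixed_hand_value(self):
        schema = self.make()
        a = pd.Series({"x": 5.0, "c": "a"})
        b = pd.Series({"x": 10.0, "c": "b"})
        assert gower_distance(a, b, schema, {"x": 10.0}) == pytest.approx(0.75)

    def test_zero_range_numeric_contributes_zero(self):
        schema = self.make()
        a = pd.Series({"x": 5.0, "c": "a"})
        b = pd.Series({"x": 5.0, "c": "b"})
        assert gower_distance(a, b, schema, {"x": 0.0}) == pytest.approx(0.5)


class TestSeparability:
    def test_two_cluster_hand_value(self):
        # class 0 at {0, 0.1}, class 1 at {1.0, 1.1}; range 1.1
        ds = one_numeric_dataset([0.0, 0.1, 1.0, 1.1], [0, 0, 1, 1])
        # brute force over all 6 pairwise distances: intra NN = 0.1/1.1 for
        # every record; inter NN = {1.0, 0.9, 0.9, 1.0}/1.1
        assert separability(ds) == pytest.approx(0.1 / 0.95)

    def test_interleaved_symmetry_near_one(self):
        xs = np.arange(20, dtype=float)
        ds = one_numeric_dataset(xs, [0, 1] * 10)
        # every NN geometry is symmetric between classes
        assert separability(ds) == pytest.approx(2.0, rel=0.2)

    def test_single_class_rejected(self):
        ds = one_numeric_dataset([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            separability(ds)

    def test_monotone_in_cluster_spacing(self):
        rng = np.random.default_rng(3)
        values = []
        for spacing in (0.5, 2.0, 5.0):
            x0 = rng.normal(0, 1, 50)
            x1 = rng.normal(spacing, 1, 50)
            ds = one_numeric_dataset(
                np.concatenate([x0, x1]), [0] * 50 + [1] * 50
            )
            values.append(separability(ds))
        assert values[0] > values[1] > values[2]

    def test_mean_of_ratios_option(self):
        ds = one_numeric_dataset([0.0, 0.1, 1.0, 1.1], [0, 0, 1, 1])
        # per-record ratios: 0.1/1.0, 0.1/0.9, 0.1/0.9, 0.1/1.0
        expected = np.mean([0.1 / 1.0, 0.1 / 0.9, 0.1 / 0.9, 0.1 / 1.0])
        assert separability(ds, aggregation="mean_of_ratios") == pytest.approx(expected)


class TestProfile:
    def test_fields_and_reproducibility(self, simple_pop, fast_settings):
        base = simple_pop.subset(range(300), id="base")
        test = simple_pop.subset(range(300, 900), id="test")
        p1 = profile(base, test, fast_settings)
        p2 = profile(base, test, fast_settings)
        assert p1 == p2
        assert p1.n0 == 300
        assert p1.n_predictors == len(base.schema.predictors)
        assert 0.0 <= p1.std_entropy <= 1.0
        assert p1.imbalance_factor >= 1.0
        assert 0.0 <= p1.baseline_auc <= 1.0

    def test_row_order_invariance(self):
        ds = random_mixed_dataset(31, n=120)
        shuffled = Dataset(
            ds.schema, ds.df.sample(frac=1, random_state=5).reset_index(drop=True)
        )
        for fn in (standardized_entropy, mutual_info_cv):
            assert fn(ds) == pytest.approx(fn(shuffled))
        assert separability(ds) == pytest.approx(separability(shuffled))
        assert imbalance_factor(ds.outcome01()) == pytest.approx(
            imbalance_factor(shuffled.outcome01())
        )
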