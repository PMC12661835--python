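"""Benefit-table construction and the random-intercept logistic model."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tabaug.benefit import (
    COVARIATES,
    build_benefit_table,
    fit_benefit_glmm,
    standardize_covariates,
    unstandardize,
)
from tabaug.complexity import ComplexityProfile
from tabaug.glmm import fit_mixed_logit
from tabaug.grid import SimulationRecord


def make_profile(dataset_id: str, n0: int, baseline: float = 0.7) -> ComplexityProfile:
    return ComplexityProfile(
        n0=n0,
        degrees_of_freedom=12,
        imbalance_factor=2.0,
        std_entropy=0.8,
        mi_cv=0.5,
        separability=0.9,
        baseline_auc=baseline,
        n_predictors=6,
    )


def make_records(dataset_id, n0, generator, aucs_by_nprime, baseline):
    recs = []
    for n_prime, aucs in aucs_by_nprime.items():
        for series_id, auc in enumerate(aucs):
            recs.append(
                SimulationRecord(
                    dataset_id=dataset_id,
                    generator=generator,
                    n0=n0,
                    n_prime=n_prime,
                    series_id=series_id,
                    auc=auc,
                    baseline_auc=baseline,
                )
            )
    return recs


class TestBuildBenefitTable:
    def test_hand_grouping_oracle(self):
        # 2 datasets x 3 n0 with hand-set AUCs; benefit iff the best
        # mean-over-series AUC at some n' exceeds baseline
        records, profiles, expected = [], {}, {}
        plan = {
            ("A", 20): ({10: [0.60, 0.62], 20: [0.72, 0.74]}, 0.70, 1),
            ("A", 50): ({10: [0.66, 0.68], 20: [0.65, 0.69]}, 0.70, 0),
            ("A", 100): ({10: [0.70, 0.70], 20: [0.71, 0.69]}, 0.70, 0),
            ("B", 20): ({10: [0.50, 0.52], 20: [0.55, 0.57]}, 0.55, 1),
            ("B", 50): ({10: [0.54, 0.56], 20: [0.52, 0.50]}, 0.56, 0),
            ("B", 100): ({10: [0.58, 0.60], 20: [0.61, 0.63]}, 0.55, 1),
        }
        for (ds, n0), (aucs, baseline, want) in plan.items():
            records += make_records(ds, n0, "seq_trees", aucs, baseline)
            profiles[(ds, n0)] = make_profile(ds, n0, baseline)
            expected[(ds, n0)] = want
        table = build_benefit_table(records, profiles)
        assert len(table) == 6
        got = {(r.dataset_id, r.n0): r.benefit for r in table}
        assert got == expected

    def test_all_below_baseline_gives_zero(self):
        records = make_records("A", 20, "bootstrap", {10: [0.5, 0.55]}, 0.70)
        table = build_benefit_table(records, {("A", 20): make_profile("A", 20)})
        assert table[0].benefit == 0

    def test_any_run_rule_differs_when_single_run_spikes(self):
        aucs = {10: [0.60, 0.80]}  # mean 0.70 = baseline, max 0.80 > baseline
        records = make_records("A", 20, "bn", aucs, 0.70)
        profiles = {("A", 20): make_profile("A", 20)}
        assert build_benefit_table(records, profiles, rule="best_mean")[0].benefit == 0
        assert build_benefit_table(records, profiles, rule="any_run")[0].benefit == 1

    def test_missing_profile_rejected(self):
        records = make_records("A", 20, "bn", {10: [0.7]}, 0.6)
        with pytest.raises(KeyError):
            build_benefit_table(records, {})


class TestStandardize:
    def make_table(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                **{c: rng.normal(5, 2, 50) for c in COVARIATES},
                "dataset_id": ["A", "B"] * 25,
                "benefit": rng.integers(0, 2, 50),
            }
        )

    def test_standardized_moments(self):
        table = self.make_table()
        std, state = standardize_covariates(table)
        for c in COVARIATES:
            assert std[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert std[c].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_back_transform_recovers(self):
        table = self.make_table()
        std, state = standardize_covariates(table)
        back = unstandardize(std, state)
        for c in COVARIATES:
            np.testing.assert_allclose(back[c], table[c], rtol=1e-10)

    def test_constant_covariate_dropped_with_warning(self):
        table = self.make_table()
        table["separability"] = 3.0
        with pytest.warns(UserWarning, match="zero variance"):
            std, state = standardize_covariates(table)
        assert "separability" not in std.columns
        assert state.dropped == ["separability"]


def simulate_clustered(seed, n_clusters=20, n_per=100, beta=(-1.5, 0.5), sigma=1.0, intercept=0.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_clusters * n_per, len(beta)))
    clusters = np.repeat(np.arange(n_clusters), n_per)
    u = rng.normal(0, sigma, n_clusters)[clusters]
    eta = intercept + X @ np.array(beta) + u
    y = (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y, clusters


class TestMixedLogit:
    def test_zero_between_cluster_variance_matches_plain_logistic(self):
        from sklearn.linear_model import LogisticRegression

        X, y, clusters = simulate_clustered(1, sigma=0.0)
        res = fit_mixed_logit(X, y, clusters, names=["a", "b"])
        lr = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        plain = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        np.testing.assert_allclose(res.estimates, plain, atol=2 * res.std_errors.max())
        assert res.sigma_u < 0.3

    def test_matches_lme4_glmer(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        X, y, clusters = simulate_clustered(42, n_clusters=30, n_per=60, beta=(-1.0, 0.6), sigma=0.8, intercept=0.3)
        res = fit_mixed_logit(X, y, clusters, names=["x1", "x2"])
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x1": X[:, 0], "x2": X[:, 1], "g": clusters}).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            d <- read.csv("{csv}")
            suppressMessages(library(lme4))
            m <- glmer(y ~ x1 + x2 + (1|g), data=d, family=binomial, nAGQ=25)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep=",")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(res.estimates, ref[:3], atol=0.05)
        assert res.sigma_u == pytest.approx(ref[3], abs=0.1)

    def test_odds_ratio_is_exp_estimate(self):
        X, y, clusters = simulate_clustered(2)
        res = fit_mixed_logit(X, y, clusters, names=["a", "b"])
        ors = res.odds_ratios()
        for name, est in zip(res.names, res.estimates):
            assert ors[name][0] == pytest.approx(np.exp(est))
            assert ors[name][1] < ors[name][0] < ors[name][2]

    def test_requires_two_clusters_and_two_outcomes(self):
        X = np.zeros((10, 1))
        with pytest.raises(ValueError):
            fit_mixed_logit(X, np.r_[np.zeros(5), np.ones(5)], np.zeros(10))
        with pytest.raises(ValueError):
            fit_mixed_logit(X, np.zeros(10), np.r_[np.zeros(5), np.ones(5)])


@pytest.fixture(scope="module")
def constructed_table():
    # benefit depends only on baseline_auc (negative) and degrees of
    # freedom (positive); other covariates are noise
    rng = np.random.default_rng(7)
    n = 600
    datasets = rng.choice([f"D{i}" for i in range(12)], n)
    baseline = rng.uniform(0.5, 0.9, n)
    dof = rng.integers(2, 40, n).astype(float)
    eta = 3.0 - 8.0 * baseline + 0.12 * dof
    benefit = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {
            "dataset_id": datasets,
            "generator": "seq_trees",
            "n0": rng.choice([20, 100, 1000], n),
            "imbalance_factor": rng.uniform(1, 5, n),
            "degrees_of_freedom": dof,
            "baseline_auc": baseline,
            "n_predictors": rng.integers(5, 20, n),
            "std_entropy": rng.uniform(0.3, 1.0, n),
            "mi_cv": rng.uniform(0, 2, n),
            "separability": rng.uniform(0.5, 1.5, n),
            "benefit": benefit,
        }
    )


class TestFitBenefitGlmm:
    def test_driving_covariates_have_smallest_p_values(self, constructed_table):
        fit = fit_benefit_glmm(constructed_table)
        p = dict(zip(fit.standardized.names, fit.standardized.p_values))
        p.pop("intercept")
        ranked = sorted(p, key=p.get)
        assert set(ranked[:2]) == {"baseline_auc", "degrees_of_freedom"}
        est = dict(zip(fit.standardized.names, fit.standardized.estimates))
        assert est["baseline_auc"] < 0
        assert est["degrees_of_freedom"] > 0

    def test_standardization_preserves_p_value_order(self, constructed_table):
        fit = fit_benefit_glmm(constructed_table)
        pu = dict(zip(fit.unstandardized.names, fit.unstandardized.p_values))
        ps = dict(zip(fit.standardized.names, fit.standardized.p_values))
        pu.pop("intercept"); ps.pop("intercept")
        assert sorted(pu, key=pu.get) == sorted(ps, key=ps.get)

    def test_coefficient_table_layout(self, constructed_table):
        fit = fit_benefit_glmm(constructed_table)
        table = fit.coefficient_table()
        assert list(table["variable"]) == ["intercept"] + COVARIATES
        np.testing.assert_allclose(
            table["odds_ratio"], np.exp(fit.unstandardized.estimates)
        )

    def test_single_cluster_rejected(self, constructed_table):
        bad = constructed_table.copy()
        bad["dataset_id"] = "only"
        with pytest.raises(ValueError):
            fit_benefit_glmm(bad)
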