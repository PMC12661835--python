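"""The augmentation-benefit table and its mixed-effects model.

For every {dataset, n0, generator} cell of a grid simulation, a binary
benefit indicator states whether augmentation improved ROC-AUC over the
un-augmented baseline.  The indicator (joined with the eight complexity
characteristics of the base dataset) is then modelled by a logistic GLMM
with a random intercept per dataset, yielding standardized and
unstandardized fixed-effect estimates, Wald p-values, and odds ratios with
95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .complexity import ComplexityProfile
from .glmm import MixedLogitResult, fit_mixed_logit
from .grid import SimulationRecord

COVARIATES = [
    "n0",
    "imbalance_factor",
    "degrees_of_freedom",
    "baseline_auc",
    "n_predictors",
    "std_entropy",
    "mi_cv",
    "separability",
]


@dataclass
class BenefitRecord:
    dataset_id: str
    generator: str
    n0: int
    imbalance_factor: float
    degrees_of_freedom: int
    baseline_auc: float
    n_predictors: int
    std_entropy: float
    mi_cv: float
    separability: float
    benefit: int

    def to_dict(self) -> dict:
        return asdict(self)


def build_benefit_table(
    records: list[SimulationRecord],
    profiles: dict[tuple[str, int], ComplexityProfile],
    rule: str = "best_mean",
) -> list[BenefitRecord]:
    """One benefit row per {dataset, n0, generator}.

    ``rule`` controls how the 10 series x 30 n' levels collapse to a single
    indicator: ``best_mean`` (default) marks benefit when the best
    mean-over-series AUC across n' levels exceeds baseline; ``any_run`` when
    any single run does; ``overall_mean`` when the grand mean does.
    """
    df = pd.DataFrame([r.to_dict() for r in records])
    df = df[~df["failed"]]
    out: list[BenefitRecord] = []
    for (dataset_id, gen, n0), g in df.groupby(["dataset_id", "generator", "n0"], sort=True):
        baseline = g["baseline_auc"].iloc[0]
        if rule == "best_mean":
            best = g.groupby("n_prime")["auc"].mean().max()
        elif rule == "any_run":
            best = g["auc"].max()
        elif rule == "overall_mean":
            best = g["auc"].mean()
        else:
            raise ValueError(f"unknown benefit rule {rule!r}")
        key = (dataset_id, int(n0))
        if key not in profiles:
            raise KeyError(f"missing complexity profile for {key}")
        prof = profiles[key]
        out.append(
            BenefitRecord(
                dataset_id=dataset_id,
                generator=gen,
                n0=int(n0),
                imbalance_factor=prof.imbalance_factor,
                degrees_of_freedom=prof.degrees_of_freedom,
                baseline_auc=prof.baseline_auc,
                n_predictors=prof.n_predictors,
                std_entropy=prof.std_entropy,
                mi_cv=prof.mi_cv,
                separability=prof.separability,
                benefit=int(best > baseline),
            )
        )
    return out


@dataclass
class ScalingState:
    means: dict[str, float]
    sds: dict[str, float]
    dropped: list[str] = field(default_factory=list)


def standardize_covariates(table: pd.DataFrame) -> tuple[pd.DataFrame, ScalingState]:
    """Center and unit-scale the covariate columns; keep the state to invert.

    Zero-variance covariates are dropped with a warning.
    """
    out = table.copy()
    means, sds, dropped = {}, {}, []
    for col in COVARIATES:
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            warnings.warn(f"covariate {col!r} has zero variance; dropped")
            dropped.append(col)
            out = out.drop(columns=[col])
            continue
        means[col], sds[col] = float(x.mean()), float(sd)
        out[col] = (x - x.mean()) / sd
    return out, ScalingState(means=means, sds=sds, dropped=dropped)


def unstandardize(table: pd.DataFrame, state: ScalingState) -> pd.DataFrame:
    out = table.copy()
    for col, mean in state.means.items():
        out[col] = out[col] * state.sds[col] + mean
    return out


@dataclass
class GlmmFit:
    unstandardized: MixedLogitResult
    standardized: MixedLogitResult

    def coefficient_table(self) -> pd.DataFrame:
        """Two-block table: estimates/p-values and ORs with 95% CIs."""
        rows = []
        ors_u = self.unstandardized.odds_ratios()
        ors_s = self.standardized.odds_ratios()
        for i, name in enumerate(self.unstandardized.names):
            rows.append(
                {
                    "variable": name,
                    "estimate": self.unstandardized.estimates[i],
                    "p_value": self.unstandardized.p_values[i],
                    "estimate_std": self.standardized.estimates[i],
                    "p_value_std": self.standardized.p_values[i],
                    "odds_ratio": ors_u[name][0],
                    "or_ci_low": ors_u[name][1],
                    "or_ci_high": ors_u[name][2],
                    "odds_ratio_std": ors_s[name][0],
                    "or_std_ci_low": ors_s[name][1],
                    "or_std_ci_high": ors_s[name][2],
                }
            )
        return pd.DataFrame(rows)


def fit_benefit_glmm(table: list[BenefitRecord] | pd.DataFrame, n_quad: int = 25) -> GlmmFit:
    """Random-intercept (per dataset) logistic fit of the benefit indicator."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame([r.to_dict() for r in table])
    if df["dataset_id"].nunique() < 2:
        raise ValueError("at least 2 dataset clusters are required")
    if df["benefit"].nunique() < 2:
        raise ValueError("benefit indicator must take both values")
    covs = [c for c in COVARIATES if c in df.columns]
    y = df["benefit"].to_numpy(dtype=float)
    clusters = df["dataset_id"].to_numpy()

    raw = fit_mixed_logit(df[covs].to_numpy(dtype=float), y, clusters, names=covs, n_quad=n_quad)
    std_df, _ = standardize_covariates(df)
    covs_std = [c for c in COVARIATES if c in std_df.columns]
    std = fit_mixed_logit(
        std_df[covs_std].to_numpy(dtype=float), y, clusters, names=covs_std, n_quad=n_quad
    )
    if raw.flagged_separation or std.flagged_separation:
        warnings.warn("possible quasi-separation: extreme estimates or unstable SEs")
    return GlmmFit(unstandardized=raw, standardized=std)
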