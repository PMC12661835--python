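"""Synthetic mixed-type populations with a binary outcome.

Real health datasets of the kind this framework targets (hospital discharge
records, adverse-event reports, population surveys) mix numeric and
categorical predictors — some with high cardinality — and carry a binary
outcome whose prevalence drives class imbalance.  This module simulates such
populations from a latent Gaussian copula:

* a latent multivariate normal draw with a configurable correlation matrix
  supplies the dependence structure;
* numeric predictors are latent coordinates (optionally transformed);
* categorical predictors slice their latent coordinate into ``k`` levels at
  quantile boundaries (equal-probability by default, or Zipf-weighted for
  imbalanced high-cardinality variables);
* the outcome follows a logistic model on predictor effects, with the
  intercept calibrated by bisection so the empirical prevalence approaches
  the configured target.

Two presets emulate the ends of the complexity range studied here: a simple
low-cardinality claims-like dataset and a complex adverse-event-report-like
dataset with several high-cardinality categoricals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Dataset, Schema, VariableSpec


@dataclass
class PopulationConfig:
    """Parameters of one simulated population.

    ``coefficients`` are log-odds effects on the outcome, one per predictor
    in order (numerics first, then categoricals).  A categorical's effect is
    applied through per-level scores spread evenly in [-1, 1] and scaled by
    its coefficient, so higher-cardinality variables carry finer-grained
    signal.  ``latent_correlation`` is either an exchangeable rho (float) or
    a full positive semi-definite matrix.
    """

    n_rows: int = 10_000
    numeric_vars: int = 3
    categorical_cardinalities: tuple[int, ...] = (3, 4)
    prevalence: float = 0.3
    latent_correlation: float | np.ndarray = 0.2
    coefficients: tuple[float, ...] | None = None
    noise_scale: float = 1.0
    zipf_levels: bool = False
    seed: int = 0

    @property
    def n_predictors(self) -> int:
        return self.numeric_vars + len(self.categorical_cardinalities)

    def correlation_matrix(self) -> np.ndarray:
        p = self.n_predictors
        if np.isscalar(self.latent_correlation):
            rho = float(self.latent_correlation)
            mat = np.full((p, p), rho)
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(self.latent_correlation, dtype=float)
            if mat.shape != (p, p):
                raise ValueError(f"correlation matrix must be {p}x{p}")
        eig = np.linalg.eigvalsh(mat)
        if eig.min() < -1e-10:
            raise ValueError("latent correlation matrix is not positive semi-definite")
        return mat

    def resolved_coefficients(self) -> np.ndarray:
        if self.coefficients is None:
            return np.ones(self.n_predictors)
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (self.n_predictors,):
            raise ValueError("one coefficient per predictor required")
        return coefs


def build_schema(config: PopulationConfig) -> Schema:
    variables = [
        VariableSpec(name=f"x{i+1}", kind="numeric") for i in range(config.numeric_vars)
    ]
    for j, k in enumerate(config.categorical_cardinalities):
        if k < 2:
            raise ValueError("categorical cardinality must be >= 2")
        variables.append(
            VariableSpec(
                name=f"c{j+1}",
                kind="categorical",
                levels=tuple(f"L{m}" for m in range(k)),
            )
        )
    variables.append(
        VariableSpec(name="outcome", kind="categorical", levels=("0", "1"), role="outcome")
    )
    return Schema(tuple(variables))


def _level_cutpoints(k: int, zipf: bool) -> np.ndarray:
    """Latent-scale boundaries for k levels (standard-normal quantiles)."""
    from scipy.stats import norm

    if zipf:
        w = 1.0 / np.arange(1, k + 1)
        probs = w / w.sum()
    else:
        probs = np.full(k, 1.0 / k)
    return norm.ppf(np.cumsum(probs)[:-1])


def generate_population(config: PopulationConfig) -> Dataset:
    """Draw one population dataset from the copula model.

    Deterministic for a fixed ``config.seed``.  The logistic intercept is
    calibrated by bisection on the realized linear predictors so that the
    expected prevalence matches ``config.prevalence`` to 1e-3.
    """
    rng = np.random.default_rng(config.seed)
    corr = config.correlation_matrix()
    p = config.n_predictors
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
    z = rng.standard_normal((config.n_rows, p)) @ chol.T

    coefs = config.resolved_coefficients()
    frame: dict[str, np.ndarray | pd.Series] = {}
    signal = np.zeros(config.n_rows)
    for i in range(config.numeric_vars):
        frame[f"x{i+1}"] = z[:, i]
        signal += coefs[i] * z[:, i]
    for j, k in enumerate(config.categorical_cardinalities):
        col = config.numeric_vars + j
        cuts = _level_cutpoints(k, config.zipf_levels)
        codes = np.searchsorted(cuts, z[:, col])
        frame[f"c{j+1}"] = pd.Series(codes).map(lambda m: f"L{m}")
        # per-level score in [-1, 1] so cardinality refines, not inflates, signal
        level_scores = np.linspace(-1.0, 1.0, k)
        signal += coefs[col] * level_scores[codes]

    if config.noise_scale > 0:
        signal = signal + config.noise_scale * rng.standard_normal(config.n_rows)

    intercept = _calibrate_intercept(signal, config.prevalence)
    prob = 1.0 / (1.0 + np.exp(-(intercept + signal)))
    y = (rng.random(config.n_rows) < prob).astype(int)
    frame["outcome"] = pd.Series(y).map(str)

    schema = build_schema(config)
    return Dataset(schema, pd.DataFrame(frame), id=f"synthpop-seed{config.seed}")


def _calibrate_intercept(signal: np.ndarray, prevalence: float, tol: float = 1e-3) -> float:
    """Bisection for the intercept giving the target expected prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")

    def expected(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + signal)))))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    mid = 0.5 * (lo + hi)
    assert abs(expected(mid) - prevalence) < tol
    return mid


# ---------------------------------------------------------------------------
# Presets


_PRESETS: dict[str, dict] = {
    # claims-like: 6 predictors, low cardinality, moderate signal
    "simple": dict(
        n_rows=100_000,
        numeric_vars=3,
        categorical_cardinalities=(2, 3, 5),
        prevalence=0.3,
        latent_correlation=0.2,
        coefficients=(0.8, 0.5, 0.3, 0.4, 0.4, 0.5),
        noise_scale=1.0,
        zipf_levels=False,
    ),
    # adverse-event-report-like: 7 predictors incl. high-cardinality categoricals
    "complex": dict(
        n_rows=100_000,
        numeric_vars=2,
        categorical_cardinalities=(4, 10, 50, 80, 120),
        prevalence=0.15,
        latent_correlation=0.25,
        coefficients=(0.4, 0.3, 0.4, 0.5, 0.8, 0.9, 1.0),
        noise_scale=1.0,
        zipf_levels=True,
    ),
}


def preset_population(name: str, n_rows: int | None = None, seed: int = 0) -> PopulationConfig:
    """Named population configurations spanning the studied complexity range.

    ``simple`` has few, low-cardinality predictors; ``complex`` has several
    categoricals with cardinality >= 50 and Zipf-imbalanced levels.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    if n_rows is not None:
        params["n_rows"] = n_rows
    return PopulationConfig(seed=seed, **params)
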