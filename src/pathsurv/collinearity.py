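"""Does the Lasso discard exactly duplicated predictors?  A simulation.

Conventional wisdom says that from a group of perfectly correlated
predictors the Lasso keeps one; sparse mutation data produce such
groups routinely (genes mutated in the same one or two patients), and
in practice path solvers frequently retain several members of a
duplicate group at once.  This module measures, per penalty value on a
common grid, how often at least one duplicate group has two or more
members selected simultaneously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = ["CollinearitySimConfig", "SimReport", "run_collinearity_simulation"]


@dataclass
class CollinearitySimConfig:
    """Duplicated-predictor Lasso simulation.

    Each replicate draws ``n_noise_predictors`` independent noise
    columns and ``n_duplicate_pairs`` signal columns each duplicated
    exactly once; the outcome carries ``effect_size`` per signal column
    (Gaussian linear model by default, or exponential-hazard survival
    with ~30% censoring).
    """

    n_samples: int = 200
    n_noise_predictors: int = 20
    n_duplicate_pairs: int = 1
    effect_size: float = 2.0
    outcome: str = "gaussian"  # {'gaussian', 'survival'}
    n_replicates: int = 50
    n_lambdas: int = 50
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_duplicate_pairs < 1:
            raise ValueError("need at least one duplicate pair")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.outcome not in ("gaussian", "survival"):
            raise ValueError(f"unknown outcome family {self.outcome!r}")


@dataclass
class SimReport:
    """Per-lambda fraction of replicates with >= 2 members of some
    duplicate group simultaneously selected."""

    lambdas: np.ndarray
    both_selected_fraction: np.ndarray
    any_lambda_all_exclusive: bool
    n_replicates: int
    same_sign_when_both: bool = True
    config: CollinearitySimConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "both_selected_fraction": self.both_selected_fraction}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambdas": self.lambdas.tolist(),
                "both_selected_fraction": self.both_selected_fraction.tolist(),
                "any_lambda_all_exclusive": self.any_lambda_all_exclusive,
                "same_sign_when_both": self.same_sign_when_both,
                "n_replicates": self.n_replicates,
            },
            indent=2,
        )


def _draw_design(config: CollinearitySimConfig, rng: np.random.Generator):
    """Design matrix with duplicate pairs first, then noise; returns
    (X, groups, eta) where eta is the true linear predictor."""
    n = config.n_samples
    bases = rng.standard_normal((n, config.n_duplicate_pairs))
    noise = rng.standard_normal((n, config.n_noise_predictors))
    cols = []
    groups = []
    for k in range(config.n_duplicate_pairs):
        cols.append(bases[:, k])
        cols.append(bases[:, k])  # exact duplicate
        groups.append((2 * k, 2 * k + 1))
    X = np.column_stack(cols + [noise]) if config.n_noise_predictors else np.column_stack(cols)
    eta = bases @ np.full(config.n_duplicate_pairs, config.effect_size)
    return X, groups, eta


def _gaussian_path_coefs(X, y, lambdas, standardize):
    Xs = X
    if standardize:
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    _, coefs, _ = lasso_path(Xs, y - y.mean(), alphas=lambdas)
    return coefs  # p x len(lambdas), lambdas descending


def _survival_path_coefs(X, time, event, lambdas, standardize):
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambdas, normalize=standardize)
    model.fit(X, Surv.from_arrays(event.astype(bool), time))
    fitted = np.asarray(model.alphas_)
    coefs = model.coef_
    if len(fitted) != len(lambdas):
        out = np.zeros((coefs.shape[0], len(lambdas)))
        for j, lam in enumerate(lambdas):
            out[:, j] = coefs[:, int(np.argmin(np.abs(fitted - lam)))]
        coefs = out
    return coefs


def _common_grid(config: CollinearitySimConfig, rng0: np.random.Generator) -> np.ndarray:
    """Lambda grid from a reference replicate, reused by all replicates."""
    X, _, eta = _draw_design(config, rng0)
    n = config.n_samples
    if config.outcome == "gaussian":
        y = eta + rng0.standard_normal(n)
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    else:
        T = rng0.exponential(1.0 / np.exp(eta))
        C = rng0.exponential(np.quantile(T, 0.7), size=n)
        probe = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=config.n_lambdas, alpha_min_ratio=0.001,
            normalize=config.standardize,
        )
        probe.fit(X, Surv.from_arrays(T <= C, np.minimum(T, C)))
        return np.asarray(probe.alphas_)
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * 1e-3), config.n_lambdas
    )


def run_collinearity_simulation(config: CollinearitySimConfig) -> SimReport:
    """Run the duplicated-predictor simulation and aggregate per lambda."""
    grid = _common_grid(config, np.random.default_rng((config.seed, 104729)))
    both = np.zeros((config.n_replicates, len(grid)), dtype=bool)
    same_sign = True
    for rep in range(config.n_replicates):
        rng = np.random.default_rng((config.seed, rep))
        X, groups, eta = _draw_design(config, rng)
        n = config.n_samples
        if config.outcome == "gaussian":
            y = eta + rng.standard_normal(n)
            coefs = _gaussian_path_coefs(X, y, grid, config.standardize)
        else:
            T = rng.exponential(1.0 / np.exp(eta))
            C = rng.exponential(np.quantile(T, 0.7), size=n)
            coefs = _survival_path_coefs(
                X, np.minimum(T, C), (T <= C).astype(int), grid, config.standardize
            )
        for i, j in groups:
            pair_both = (coefs[i] != 0) & (coefs[j] != 0)
            both[rep] |= pair_both
            if pair_both.any():
                signs = np.sign(coefs[i][pair_both]) == np.sign(coefs[j][pair_both])
                same_sign &= bool(signs.all())
    fraction = both.mean(axis=0)
    return SimReport(
        lambdas=grid,
        both_selected_fraction=fraction,
        any_lambda_all_exclusive=bool((fraction == 0).any()),
        n_replicates=config.n_replicates,
        same_sign_when_both=same_sign,
        config=config,
    )
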