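"""Cox proportional hazards fitting, penalized and unpenalized.

``CoxLasso`` fits an L1-penalized Cox partial-likelihood path (glmnet
style, via scikit-survival's coordinate-descent solver) and selects the
penalty weight lambda by inner cross-validation of the Verweij–van
Houwelingen partial-likelihood deviance.  ``CoxPH`` is the unpenalized
Newton fit (Efron ties, via lifelines) with explicit detection of
aliased -- exactly collinear -- predictors, which receive no estimate,
mirroring how standard survival software reports them.  Both follow the
model/results pattern: construct with data, call ``fit()``, read the
results object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _lifelines_cindex
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .containers import FeatureMatrix, SurvivalData

logger = logging.getLogger(__name__)

__all__ = [
    "CoxLasso",
    "CoxLassoResults",
    "CoxPH",
    "CoxPHResults",
    "univariable_cox",
    "concordance_index",
    "breslow_loglik",
]

_ALIAS_TOL = 1e-9


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FeatureMatrix):
        return X.values.astype(float)
    return pd.DataFrame(X).astype(float)


def concordance_index(risk, y: SurvivalData) -> float:
    """Harrell's concordance index of a risk score against outcomes.

    Over comparable pairs (the earlier time is an observed event), the
    fraction in which the earlier-event sample has the higher risk; risk
    ties count 0.5.  1 is perfect ranking, 0.5 is random.  Raises if no
    pair is comparable (e.g. everything censored).
    """
    risk = np.asarray(risk, dtype=float)
    if risk.shape[0] != y.n_samples:
        raise ValueError("risk vector and survival data are misaligned")
    try:
        # lifelines counts higher prediction = longer survival, so negate
        return float(_lifelines_cindex(y.time, -risk, y.event))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs (all samples censored?)") from exc


def breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox log partial likelihood (Breslow ties) at linear predictor eta."""
    order = np.argsort(-time, kind="stable")
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    m = eta_o.max() if len(eta_o) else 0.0
    cum = np.cumsum(np.exp(eta_o - m))
    # risk set of an event at time t is everyone with t_j >= t, so for
    # tied times use the cumulative sum at the end of the tie run
    last_of_tie = np.searchsorted(-t_o, -t_o, side="right") - 1
    log_risk = np.log(cum[last_of_tie]) + m
    return float(np.sum(e_o * (eta_o - log_risk)))


@dataclass
class CoxLassoResults:
    """Fitted L1-penalized Cox path with a CV-selected lambda."""

    lambda_grid: np.ndarray
    cv_error_per_lambda: np.ndarray  # mean V&VH deviance across inner folds
    lambda_selected: float
    coefficients: pd.Series  # original scale, at lambda_selected
    inner_folds: int
    seed: int
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(self.coefficients.index[self.coefficients != 0])

    def predict(self, X) -> np.ndarray:
        """Linear predictor (log relative hazard) for new samples."""
        df = _as_frame(X)
        beta = self.coefficients.reindex(df.columns).fillna(0.0)
        return df.to_numpy() @ beta.to_numpy()

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"coef": self.coefficients})
        df["selected"] = df["coef"] != 0
        return df


class CoxLasso:
    """L1-penalized Cox model with inner-CV lambda selection.

    Parameters
    ----------
    X : FeatureMatrix or DataFrame (samples x predictors)
    y : SurvivalData aligned with X's samples
    inner_folds : folds of the internal CV used to pick lambda
    seed : controls the fold assignment (event-stratified)
    n_lambdas, lambda_min_ratio : path grid -- 100 log-spaced values
        from the smallest lambda giving the empty model down to 1e-3 of it
    standardize : standardize predictors internally; coefficients are
        returned on the original scale either way
    """

    def __init__(
        self,
        X,
        y: SurvivalData,
        inner_folds: int = 10,
        seed: int = 0,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
        standardize: bool = True,
    ) -> None:
        self.X = _as_frame(X)
        self.y = y
        if list(self.X.index) != y.sample_ids:
            self.y = y.subset(list(self.X.index))
        self.inner_folds = inner_folds
        self.seed = seed
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize

    def fit(self) -> CoxLassoResults:
        X, y = self.X, self.y
        if y.n_events < 2:
            raise ValueError("penalized Cox fit needs at least 2 events")
        variances = X.var(axis=0, ddof=0)
        dropped = list(X.columns[variances == 0])
        if dropped:
            logger.warning("dropping %d zero-variance predictors", len(dropped))
            X = X.drop(columns=dropped)
        if X.shape[1] == 0:
            raise ValueError("all predictors are constant")

        Xa = X.to_numpy()
        surv = Surv.from_arrays(y.event.astype(bool), y.time)
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            n_alphas=self.n_lambdas,
            alpha_min_ratio=self.lambda_min_ratio,
            normalize=self.standardize,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path.fit(Xa, surv)
        grid = np.asarray(path.alphas_)

        folds = _stratified_folds(y.event, self.inner_folds, self.seed)
        cv_dev = np.zeros((len(folds), len(grid)))
        time, event = y.time, y.event
        for k, test_idx in enumerate(folds):
            train_mask = np.ones(len(time), dtype=bool)
            train_mask[test_idx] = False
            sub = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=grid, normalize=self.standardize
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub.fit(Xa[train_mask], Surv.from_arrays(
                    event[train_mask].astype(bool), time[train_mask]))
            coefs = _coefs_on_grid(sub, grid)
            for a, beta in enumerate(coefs.T):
                eta = Xa @ beta
                ll_all = breslow_loglik(eta, time, event)
                ll_train = breslow_loglik(
                    eta[train_mask], time[train_mask], event[train_mask]
                )
                cv_dev[k, a] = -2.0 * (ll_all - ll_train)
        mean_dev = cv_dev.mean(axis=0)
        best = int(np.argmin(mean_dev))
        lambda_selected = float(grid[best])
        full_coefs = _coefs_on_grid(path, grid)
        coefficients = pd.Series(full_coefs[:, best], index=X.columns)
        coefficients = coefficients.reindex(self.X.columns).fillna(0.0)
        return CoxLassoResults(
            lambda_grid=grid,
            cv_error_per_lambda=mean_dev,
            lambda_selected=lambda_selected,
            coefficients=coefficients,
            inner_folds=self.inner_folds,
            seed=self.seed,
            dropped_constant=dropped,
        )

    def fit_at(self, lam: float) -> pd.Series:
        """Coefficients of the whole-data fit at the single penalty ``lam``.

        Solved directly at ``lam`` with a tight tolerance (the automatic
        path can stop early, before small penalties, when the deviance
        saturates).
        """
        X, y = self.X, self.y
        variances = X.var(axis=0, ddof=0)
        X = X.loc[:, variances > 0]
        surv = Surv.from_arrays(y.event.astype(bool), y.time)
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[lam], normalize=self.standardize,
            tol=1e-9, max_iter=200000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X.to_numpy(), surv)
        out = pd.Series(model.coef_[:, -1], index=X.columns)
        return out.reindex(self.X.columns).fillna(0.0)


def _coefs_on_grid(model: CoxnetSurvivalAnalysis, grid: np.ndarray) -> np.ndarray:
    """Coefficient matrix (p x len(grid)), tolerant of solver-truncated paths."""
    fitted = np.asarray(model.alphas_)
    coefs = model.coef_
    if len(fitted) == len(grid):
        return coefs
    out = np.zeros((coefs.shape[0], len(grid)))
    for j, lam in enumerate(grid):
        idx = int(np.argmin(np.abs(fitted - lam)))
        out[:, j] = coefs[:, idx]
    return out


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Event-stratified fold assignment; returns test-index arrays."""
    rng = np.random.default_rng(seed)
    idx_event = rng.permutation(np.flatnonzero(event == 1))
    idx_cens = rng.permutation(np.flatnonzero(event == 0))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for pool in (idx_event, idx_cens):
        for i, sample in enumerate(pool):
            folds[i % n_folds].append(int(sample))
    return [np.sort(np.array(f, dtype=int)) for f in folds if len(f)]


def _find_aliased(X: np.ndarray, tol: float = _ALIAS_TOL) -> np.ndarray:
    """Boolean mask of columns exactly dependent on earlier kept columns.

    Columns are centered first, so constants are aliased too.  Earlier
    columns win: within a dependent group only the first is estimable.
    """
    Xc = X - X.mean(axis=0)
    n, p = Xc.shape
    aliased = np.zeros(p, dtype=bool)
    basis: list[np.ndarray] = []
    for j in range(p):
        col = Xc[:, j].copy()
        norm0 = np.linalg.norm(col)
        if norm0 <= tol:
            aliased[j] = True
            continue
        for q in basis:
            col -= (q @ col) * q
        # re-orthogonalize once for numerical safety
        for q in basis:
            col -= (q @ col) * q
        norm = np.linalg.norm(col)
        if norm <= max(tol, 1e-9 * norm0):
            aliased[j] = True
        else:
            basis.append(col / norm)
    return aliased


@dataclass
class CoxPHResults:
    """Unpenalized multivariable Cox fit.

    Aliased (exactly collinear) predictors carry no estimate: their
    hazard ratio, standard error and p-value are NaN, matching the NA
    reporting of standard survival software.
    """

    table: pd.DataFrame  # index: predictors; coef, hazard_ratio, se_coef, p_value, aliased
    converged: bool
    diagnostic: str = ""

    @property
    def aliased(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["aliased"]])

    @property
    def hazard_ratios(self) -> dict[str, float]:
        return self.table["hazard_ratio"].to_dict()

    @property
    def se_coef(self) -> dict[str, float]:
        return self.table["se_coef"].to_dict()

    @property
    def p_values(self) -> dict[str, float]:
        return self.table["p_value"].to_dict()

    def summary(self) -> pd.DataFrame:
        return self.table.copy()


class CoxPH:
    """Unpenalized Cox proportional hazards model (Efron tie handling).

    Exactly collinear columns beyond the first of each dependent group
    are flagged aliased and excluded from estimation; Wald standard
    errors and p-values are reported for the rest.  Non-convergence
    (monotone likelihood from e.g. a predictor mutated only in censored
    samples) is reported on the results object, not raised.
    """

    def __init__(self, X, y: SurvivalData) -> None:
        self.X = _as_frame(X)
        self.y = y
        if list(self.X.index) != y.sample_ids:
            self.y = y.subset(list(self.X.index))

    def fit(self) -> CoxPHResults:
        X, y = self.X, self.y
        cols = list(X.columns)
        table = pd.DataFrame(
            {
                "coef": np.nan,
                "hazard_ratio": np.nan,
                "se_coef": np.nan,
                "p_value": np.nan,
                "aliased": False,
            },
            index=pd.Index(cols, name="predictor"),
        )
        if not cols:
            return CoxPHResults(table, converged=True, diagnostic="empty model")
        aliased = _find_aliased(X.to_numpy())
        table.loc[np.asarray(cols)[aliased], "aliased"] = True
        keep = [c for c, a in zip(cols, aliased) if not a]
        if not keep:
            return CoxPHResults(table, converged=True, diagnostic="all predictors aliased")

        frame = X[keep].copy()
        frame["time"] = y.time
        frame["event"] = y.event
        fitter = CoxPHFitter()
        diagnostic = ""
        converged = True
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fitter.fit(frame, duration_col="time", event_col="event")
            conv = [w for w in caught if "convergence" in str(w.message).lower()
                    or "variance" in str(w.message).lower()]
            if conv:
                converged = False
                diagnostic = str(conv[0].message)
            table.loc[keep, "coef"] = fitter.params_[keep].to_numpy()
            table.loc[keep, "hazard_ratio"] = np.exp(fitter.params_[keep].to_numpy())
            table.loc[keep, "se_coef"] = fitter.standard_errors_[keep].to_numpy()
            table.loc[keep, "p_value"] = fitter.summary.loc[keep, "p"].to_numpy()
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            converged = False
            diagnostic = f"fit failed: {exc}"
        return CoxPHResults(table, converged=converged, diagnostic=diagnostic)


def univariable_cox(X, y: SurvivalData) -> dict[str, CoxPHResults]:
    """One single-predictor Cox fit per column; failures are recorded
    in the per-predictor results, never raised."""
    df = _as_frame(X)
    return {col: CoxPH(df[[col]], y).fit() for col in df.columns}
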