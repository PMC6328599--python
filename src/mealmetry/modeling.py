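"""Intake models: zero-intercept regression, LOSO CV, forward selection.

Five model families (full, bite, chew, swallow, sensor) are built for each
target (mass in g, energy in kcal).  Features are chosen by greedy forward
selection minimising the mean absolute percentage error (MAPE) of
leave-one-subject-out (LOSO) cross-validated predictions; the final model is
a multiple linear regression through the origin refit on all meals.

Selection runs once on the whole dataset and the same features are then used
in every LOSO fold (selection is not re-nested per fold); ``nested=True``
on :func:`build_model_family` re-selects inside each fold for a
leakage-free error estimate at extra cost.

Inference conventions for the no-intercept fit: df_resid = n - p (no
intercept consumes no degree of freedom), two-sided p-values from the
central t distribution, and the *uncentered* R-squared
``1 - SSE / sum(y^2)`` adjusted with total df n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .features import FAMILY_POOLS

__all__ = [
    "ModelFit",
    "SelectionTrace",
    "FamilyResult",
    "fit_zero_intercept",
    "predict",
    "loso_predictions",
    "mean_ape",
    "forward_select",
    "build_model_family",
    "TARGETS",
    "FAMILIES",
]

TARGETS = ("mass_g", "energy_kcal")
FAMILIES = ("full", "bite", "chew", "swallow", "sensor")


@dataclass
class ModelFit:
    """A zero-intercept multiple regression with coefficient inference."""

    target: str
    feature_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    adj_R2: float
    root_MSE: float
    n_meals: int

    @property
    def df_resid(self) -> int:
        return self.n_meals - len(self.feature_names)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Coefficient": self.coefficients,
                "SE": self.standard_errors,
                "t value": self.t_values,
                "P value": self.p_values,
            },
            index=self.feature_names,
        )


@dataclass
class SelectionTrace:
    """The forward-selection path: (step, feature added, LOSO MAPE after adding)."""

    pool_name: str
    steps: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [name for _, name, _ in self.steps]


@dataclass
class FamilyResult:
    """Everything produced for one (family, target) model."""

    family: str
    target: str
    trace: SelectionTrace
    fit: ModelFit
    loso_estimates: pd.Series  # indexed like the dataset rows


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; the message names the columns."""


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns: {bad}"
        )


def fit_zero_intercept(X, y, feature_names=None, target: str = "y") -> ModelFit:
    """Least-squares fit of ``y ~ X`` with the intercept fixed at 0.

    Coefficients, SEs, t and two-sided p-values come from statsmodels OLS
    without a constant term; root MSE is ``sqrt(SSE / (n - p))`` and adj-R2
    uses the uncentered convention for through-the-origin models.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    feature_names = list(feature_names)
    if not (n > p >= 1):
        raise ValueError(f"need n > p >= 1, got n={n}, p={p}")
    _check_rank(X, feature_names)

    res = sm.OLS(y, X).fit()
    sse = float(res.ssr)
    root_mse = float(np.sqrt(sse / (n - p)))
    tss = float(np.sum(y**2))
    r2u = 1.0 - sse / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2u) * n / (n - p)
    return ModelFit(
        target=target,
        feature_names=feature_names,
        coefficients=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        t_values=np.asarray(res.tvalues, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        adj_R2=float(adj_r2),
        root_MSE=root_mse,
        n_meals=n,
    )


def predict(fit: ModelFit, X) -> np.ndarray:
    """Through-the-origin predictions ``X @ beta``; negative values are kept."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(fit.feature_names):
        raise ValueError(
            f"X has {X.shape[1]} columns, fit has {len(fit.feature_names)} features"
        )
    return X @ fit.coefficients


def _lstsq_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficiencyError("rank-deficient training design in fold")
    return beta


def loso_predictions(table: pd.DataFrame, feature_names, target: str) -> pd.Series:
    """Out-of-fold predictions under leave-one-subject-out cross-validation.

    For each subject, a zero-intercept model is trained on every other
    subject's meals and predicts the held-out subject's meals; no meal ever
    enters its own training fold.
    """
    feature_names = list(feature_names)
    subjects = table["subject_id"]
    uniq = subjects.unique()
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    X = table[feature_names].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    out = np.empty(len(table))
    p = len(feature_names)
    for s in uniq:
        test = (subjects == s).to_numpy()
        train = ~test
        n_train = int(train.sum())
        if n_train <= p:
            raise ValueError(
                f"fold for subject {s!r}: training n={n_train} <= p={p}"
            )
        beta = _lstsq_beta(X[train], y[train])
        out[test] = X[test] @ beta
    return pd.Series(out, index=table.index, name=f"loso_{target}")


def mean_ape(estimates, actuals) -> tuple[np.ndarray, float, float]:
    """Per-meal absolute percentage errors with their mean and sample SD.

    APE = |(estimated - actual) / actual| * 100; undefined when an actual
    value is 0.
    """
    est = np.asarray(estimates, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if est.shape != act.shape:
        raise ValueError("estimates and actuals must have the same length")
    if np.any(act == 0):
        raise ValueError("APE undefined for an actual value of 0")
    ape = np.abs((est - act) / act) * 100.0
    sd = float(np.std(ape, ddof=1)) if ape.size > 1 else 0.0
    return ape, float(ape.mean()), sd


def _loso_mape(table: pd.DataFrame, feature_names, target: str) -> float:
    est = loso_predictions(table, feature_names, target)
    _, mape, _ = mean_ape(est.to_numpy(), table[target].to_numpy(dtype=float))
    return mape


def forward_select(
    table: pd.DataFrame,
    pool,
    target: str,
    max_k: int = 6,
    pool_name: str = "custom",
) -> SelectionTrace:
    """Greedy forward selection minimising LOSO MAPE.

    At each step the pool feature whose inclusion gives the lowest mean LOSO
    APE is added; selection stops when no candidate strictly improves the
    criterion or ``max_k`` features are selected.  Ties break in pool
    (registry) order, so the procedure is deterministic.
    """
    pool = list(pool)
    if not pool or max_k < 1:
        raise ValueError("pool must be non-empty and max_k >= 1")
    trace = SelectionTrace(pool_name=pool_name)
    selected: list[str] = []
    best_mape = np.inf
    while len(selected) < max_k:
        step_best: tuple[float, str] | None = None
        any_ok = False
        for name in pool:
            if name in selected:
                continue
            try:
                mape = _loso_mape(table, selected + [name], target)
            except (RankDeficiencyError, ValueError):
                continue
            any_ok = True
            if step_best is None or mape < step_best[0]:
                step_best = (mape, name)
        if not any_ok:
            if not selected:
                raise RankDeficiencyError(
                    "every single-feature model failed to fit (rank)"
                )
            break
        assert step_best is not None
        mape, name = step_best
        if mape >= best_mape:
            break
        selected.append(name)
        best_mape = mape
        trace.steps.append((len(selected), name, mape))
    return trace


def build_model_family(
    table: pd.DataFrame,
    family: str,
    target: str,
    max_k: int = 6,
    nested: bool = False,
) -> FamilyResult:
    """Select features from a family pool, refit on all meals, keep LOSO estimates.

    With ``nested=True`` the forward selection is rerun inside each LOSO fold
    (the held-out subject never influences its own feature choice) and the
    reported LOSO estimates come from those per-fold models; the final
    coefficient table still uses the whole-dataset selection.
    """
    if family not in FAMILY_POOLS:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    pool = FAMILY_POOLS[family]
    trace = forward_select(table, pool, target, max_k=max_k, pool_name=family)
    names = trace.selected
    fit = fit_zero_intercept(
        table[names].to_numpy(dtype=float),
        table[target].to_numpy(dtype=float),
        feature_names=names,
        target=target,
    )
    if nested:
        est = _nested_loso(table, pool, target, max_k)
    else:
        est = loso_predictions(table, names, target)
    return FamilyResult(family=family, target=target, trace=trace, fit=fit,
                        loso_estimates=est)


def _nested_loso(table: pd.DataFrame, pool, target: str, max_k: int) -> pd.Series:
    out = pd.Series(np.empty(len(table)), index=table.index, name=f"loso_{target}")
    for s in table["subject_id"].unique():
        test = table["subject_id"] == s
        train_tbl = table.loc[~test]
        tr = forward_select(train_tbl, pool, target, max_k=max_k, pool_name="nested")
        beta = _lstsq_beta(
            train_tbl[tr.selected].to_numpy(dtype=float),
            train_tbl[target].to_numpy(dtype=float),
        )
        out.loc[test] = table.loc[test, tr.selected].to_numpy(dtype=float) @ beta
    return out
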