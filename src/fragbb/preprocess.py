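"""Descriptor/endpoint scaling, variance filtering and descriptor selection.

Fragment counts are integers with strongly non-normal distributions, and
small changes near zero matter; linear [0, 1] min-max scaling (applied
per column, to descriptors and to the endpoint alike) preserves that
structure and is the default.  Selection offers univariate scoring
(F-value or mutual information), recursive feature elimination over several
base regressors, and the default stepwise procedure in which a partial
least squares fit on the already-selected subset defines a residual
endpoint and the next descriptor maximizes a relevance score against that
residual.

Scalers and selectors are fitted on training rows only; applying them to
held-out rows never touches held-out endpoint values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE, f_regression, mutual_info_regression
from sklearn.linear_model import ElasticNet, Lasso
from sklearn.preprocessing import (
    MinMaxScaler,
    QuantileTransformer,
    RobustScaler,
    StandardScaler,
)
from sklearn.svm import LinearSVR
from sklearn.utils.validation import check_is_fitted

SCALER_METHODS = ("range01", "zscore", "robust_median_iqr", "quantile")
SELECTION_METHODS = ("univariate_f", "univariate_mi", "rfe", "stepwise_pls")

MI_N_NEIGHBORS = 3  # fixed nearest-neighbor count of the MI estimator


@dataclass(frozen=True)
class ScalerSpec:
    """Per-column scaling specification."""

    method: str = "range01"

    def __post_init__(self):
        if self.method not in SCALER_METHODS:
            raise ValueError(f"method must be one of {SCALER_METHODS}")


class FittedScaler:
    """Invertible per-column scaler fitted on training rows only.

    ``range01`` maps each column's training minimum to 0 and maximum to 1;
    a constant column maps to 0 by convention.  Out-of-range prediction
    inputs may fall outside [0, 1] and are not clipped here.
    """

    def __init__(self, spec: ScalerSpec, n_rows: int):
        self.spec = spec
        self.n_rows = n_rows

    @classmethod
    def fit(cls, X: np.ndarray, spec: ScalerSpec = ScalerSpec(),
            seed: int = 0) -> "FittedScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 1:
            raise ValueError("need at least one row to fit a scaler")
        self = cls(spec, X.shape[0])
        if spec.method == "range01":
            self._impl = MinMaxScaler()
        elif spec.method == "zscore":
            self._impl = StandardScaler()
        elif spec.method == "robust_median_iqr":
            self._impl = RobustScaler()
        else:
            self._impl = QuantileTransformer(
                n_quantiles=min(1000, X.shape[0]), random_state=seed
            )
        self._impl.fit(X)
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        out = self._impl.transform(X[:, None] if squeeze else X)
        return out[:, 0] if squeeze else out

    def invert(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        out = self._impl.inverse_transform(X[:, None] if squeeze else X)
        return out[:, 0] if squeeze else out


def fit_scaler(matrix_columns: np.ndarray, spec: ScalerSpec = ScalerSpec(),
               seed: int = 0) -> FittedScaler:
    """Fit a per-column scaler; thin functional wrapper over FittedScaler.fit."""
    return FittedScaler.fit(matrix_columns, spec, seed)


def variance_filter(matrix: np.ndarray, threshold: float = 1e-6) -> np.ndarray:
    """Indices of columns whose variance is at least ``threshold``."""
    var = np.var(np.asarray(matrix, dtype=float), axis=0)
    return np.flatnonzero(var >= threshold)


@dataclass
class SelectionResult:
    """Outcome of a descriptor selection run."""

    method: str
    selected_indices: list[int]
    scores: np.ndarray
    early_stop: bool = False

    def __post_init__(self):
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected indices must be distinct")


def _top_k_stable(scores: np.ndarray, k: int) -> list[int]:
    """Top-k indices by score, ties broken by ascending column index.

    Columns are pre-sorted by canonical fragment key, so index order is
    key order.
    """
    order = np.argsort(-scores, kind="stable")
    return [int(i) for i in order[:k]]


def _univariate_scores(X, y, score: str, seed: int = 0) -> np.ndarray:
    if score == "f_value":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns yield 0/0
            f, _ = f_regression(X, y)
        return np.nan_to_num(f, nan=0.0)
    if score == "mutual_information":
        return mutual_info_regression(
            X, y, n_neighbors=MI_N_NEIGHBORS, random_state=seed
        )
    raise ValueError(f"unknown score {score!r}")


def select_univariate(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    score: Literal["f_value", "mutual_information"] = "f_value",
    seed: int = 0,
) -> SelectionResult:
    """Top-k columns by univariate relevance to the endpoint."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[1]:
        warnings.warn(
            f"requested {k} descriptors but only {X.shape[1]} available",
            stacklevel=2,
        )
        k = X.shape[1]
    scores = _univariate_scores(X, y, score, seed)
    method = "univariate_f" if score == "f_value" else "univariate_mi"
    return SelectionResult(method, _top_k_stable(scores, k), scores)


class _PLSForRFE(BaseEstimator, RegressorMixin):
    """PLS regressor exposing |coefficients| as importances for RFE."""

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y):
        self.pls_ = PLSRegression(
            n_components=min(self.n_components, X.shape[1], X.shape[0] - 1)
        )
        self.pls_.fit(X, y)
        self.feature_importances_ = np.abs(np.ravel(self.pls_.coef_))
        return self

    def predict(self, X):
        return np.ravel(self.pls_.predict(X))


def _rfe_base(base_model: str, seed: int):
    if base_model == "pls":
        return _PLSForRFE()
    if base_model == "random_forest":
        return RandomForestRegressor(n_estimators=100, random_state=seed)
    if base_model == "linear_svm":
        return LinearSVR(random_state=seed, max_iter=5000, dual="auto")
    if base_model == "elastic_net":
        return ElasticNet(random_state=seed)
    if base_model == "lasso":
        return Lasso(random_state=seed)
    raise ValueError(f"unknown base model {base_model!r}")


def select_rfe(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    base_model: str = "pls",
    step: int | float = 0.1,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination down to k descriptors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k >= X.shape[1]:
        return SelectionResult("rfe", list(range(X.shape[1])),
                               np.ones(X.shape[1]))
    try:
        rfe = RFE(_rfe_base(base_model, seed), n_features_to_select=k, step=step)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfe.fit(X, y)
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - base model diagnostics
        raise RuntimeError(f"RFE base model {base_model} failed: {exc}") from exc
    selected = [int(i) for i in np.flatnonzero(rfe.support_)]
    # lower ranking = retained longer; expose as a relevance score
    scores = 1.0 / rfe.ranking_.astype(float)
    return SelectionResult("rfe", selected, scores)


def select_stepwise_pls(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    score: Literal["f_value", "mutual_information"] = "f_value",
    max_pls_components: int = 5,
    residual_tol: float = 1e-12,
    seed: int = 0,
) -> SelectionResult:
    """Stepwise residual-driven selection with a PLS working model.

    Starting from the empty subset, each step fits a PLS regression on the
    currently selected columns, forms the residual endpoint, and adds the
    not-yet-selected column with the highest relevance score against that
    residual; stops after ``k`` descriptors, or early if the residual
    variance degenerates (near-exact fit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_cols = X.shape[1]
    if k > n_cols:
        warnings.warn(
            f"requested {k} descriptors but only {n_cols} available",
            stacklevel=2,
        )
        k = n_cols
    selected: list[int] = []
    scores = np.zeros(n_cols)
    residual = y.copy()
    early_stop = False
    remaining = np.arange(n_cols)
    while len(selected) < k:
        if np.var(residual) < residual_tol:
            early_stop = True
            break
        cand_scores = _univariate_scores(X[:, remaining], residual, score, seed)
        best_pos = int(np.argsort(-cand_scores, kind="stable")[0])
        j = int(remaining[best_pos])
        selected.append(j)
        scores[j] = cand_scores[best_pos]
        remaining = np.delete(remaining, best_pos)
        n_comp = min(max_pls_components, len(selected), X.shape[0] - 1)
        pls = PLSRegression(n_components=n_comp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(X[:, selected], y)
        residual = y - np.ravel(pls.predict(X[:, selected]))
        if remaining.size == 0:
            break
    return SelectionResult("stepwise_pls", selected, scores, early_stop)


def run_selection(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    method: str = "stepwise_pls",
    seed: int = 0,
    **kwargs,
) -> SelectionResult:
    """Dispatch to the configured selection method."""
    if method == "univariate_f":
        return select_univariate(X, y, k, "f_value", seed)
    if method == "univariate_mi":
        return select_univariate(X, y, k, "mutual_information", seed)
    if method == "rfe":
        return select_rfe(X, y, k, seed=seed, **kwargs)
    if method == "stepwise_pls":
        return select_stepwise_pls(X, y, k, seed=seed, **kwargs)
    raise ValueError(f"unknown selection method {method!r}")


class StepwisePLSSelector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer around the stepwise PLS selection."""

    def __init__(self, k: int = 200, score: str = "f_value", seed: int = 0):
        self.k = k
        self.score = score
        self.seed = seed

    def fit(self, X, y):
        result = select_stepwise_pls(X, y, self.k, self.score, seed=self.seed)
        self.selection_ = result
        self.selected_indices_ = np.asarray(result.selected_indices, dtype=int)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        return np.asarray(X)[:, self.selected_indices_]


def selection_to_text(result: SelectionResult, keys: Sequence[str]) -> str:
    """Serialize a selection as 'fragment-key<TAB>score' lines."""
    lines = [
        f"{keys[i]}\t{result.scores[i]:.6g}" for i in result.selected_indices
    ]
    return "\n".join(lines) + "\n"
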