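"""Repeated double cross-validation and ensemble construction.

The dataset is split in an outer loop into NO subsets of near-equal size;
each outer subset in turn serves as a validation set for NI networks built
in the inner loop by splitting the remaining compounds into NI subsets,
training on NI−1 of them and early-stopping on the held-out one.  The whole
scheme can be repeated NR times with fresh shuffles.  Each compound thus
receives an out-of-fold prediction (the mean of the NI inner networks of
its outer fold) per repetition, consolidated into the cross-validation
statistics

    Q²      = 1 − PRESS / SS
    RMSEcv  = sqrt(PRESS / N)

where PRESS is the sum of squared out-of-fold prediction errors on the
original endpoint scale, SS the sum of squared deviations of the endpoint
from its mean, and N the number of compounds.  The NR×NO×NI trained
networks, each with its fitted scalers and selected descriptor subset,
form the prediction ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nnet import SELUNetRegressor
from .preprocess import FittedScaler, ScalerSpec, run_selection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DCVSpec:
    """Double cross-validation geometry: NO outer folds, NI inner folds,
    NR repetitions."""

    NO: int = 5
    NI: int = 4
    NR: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.NO < 2 or self.NI < 2 or self.NR < 1:
            raise ValueError("need NO >= 2, NI >= 2, NR >= 1")


@dataclass
class FoldPlan:
    """Index partitions: outer[r][o] and inner[r][o][i] arrays of compound
    indices."""

    outer: list[list[np.ndarray]]
    inner: list[list[list[np.ndarray]]]

    def validate(self, n: int) -> None:
        for r, folds in enumerate(self.outer):
            all_idx = np.concatenate(folds)
            if sorted(all_idx) != list(range(n)):
                raise ValueError(f"outer folds of repetition {r} do not partition")
            sizes = [len(f) for f in folds]
            if max(sizes) - min(sizes) > 1:
                raise ValueError("outer fold sizes differ by more than 1")
            for o, fold in enumerate(folds):
                rest = np.setdiff1d(np.arange(n), fold)
                inner_all = np.concatenate(self.inner[r][o])
                if sorted(inner_all) != sorted(rest):
                    raise ValueError(
                        f"inner folds of rep {r} outer {o} do not partition"
                    )


def make_fold_plan(n: int, spec: DCVSpec) -> FoldPlan:
    """Random near-equal partitions, independently reshuffled per repetition."""
    if n < spec.NO * spec.NI:
        raise ValueError(f"n={n} too small for {spec.NO}x{spec.NI} folds")
    rng = np.random.default_rng(spec.seed)
    outer, inner = [], []
    for _ in range(spec.NR):
        perm = rng.permutation(n)
        outer_folds = [np.sort(f) for f in np.array_split(perm, spec.NO)]
        inner_per_outer = []
        for fold in outer_folds:
            rest = np.setdiff1d(np.arange(n), fold)
            rest = rng.permutation(rest)
            inner_per_outer.append(
                [np.sort(f) for f in np.array_split(rest, spec.NI)]
            )
        outer.append(outer_folds)
        inner.append(inner_per_outer)
    return FoldPlan(outer, inner)


@dataclass
class CVResult:
    """Consolidated double cross-validation statistics."""

    predictions: np.ndarray  # (NR, N) out-of-fold predictions
    consolidated: np.ndarray  # (N,) predictions averaged over repetitions
    endpoint: np.ndarray
    PRESS: float
    SS: float
    N: int
    Q2: float
    RMSEcv: float

    def summary(self) -> dict:
        return {
            "N": self.N,
            "PRESS": self.PRESS,
            "SS": self.SS,
            "Q2": self.Q2,
            "RMSEcv": self.RMSEcv,
        }


def consolidate(predictions: np.ndarray, endpoint: np.ndarray) -> CVResult:
    """Compute PRESS, SS, Q² and RMSEcv from out-of-fold predictions.

    ``predictions`` has one row per repetition; repetitions are averaged
    per compound before the error sums, so N stays the compound count.
    Predictions and endpoint are on the original (unscaled) LogBB scale.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    endpoint = np.asarray(endpoint, dtype=float).ravel()
    if predictions.shape[1] != endpoint.shape[0]:
        raise ValueError("prediction/endpoint length mismatch")
    if np.isnan(predictions).any():
        raise ValueError("every compound needs an out-of-fold prediction")
    SS = float(np.sum((endpoint - endpoint.mean()) ** 2))
    if SS == 0:
        raise ValueError("constant endpoint: SS = 0")
    consolidated = predictions.mean(axis=0)
    PRESS = float(np.sum((consolidated - endpoint) ** 2))
    N = endpoint.shape[0]
    return CVResult(
        predictions=predictions,
        consolidated=consolidated,
        endpoint=endpoint,
        PRESS=PRESS,
        SS=SS,
        N=N,
        Q2=1.0 - PRESS / SS,
        RMSEcv=float(np.sqrt(PRESS / N)),
    )


@dataclass
class EnsembleMember:
    """One trained network with its preprocessing state and fold provenance."""

    net: SELUNetRegressor
    x_scaler: FittedScaler
    y_scaler: FittedScaler
    selected: np.ndarray  # indices into the (variance-filtered) feature matrix
    provenance: tuple[int, int, int]  # (repetition, outer fold, inner fold)
    train_rows: np.ndarray
    valid_rows: np.ndarray
    ok: bool = True

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Predict on the original endpoint scale from the full feature
        matrix (original count scale)."""
        Xs = self.x_scaler.apply(np.asarray(X, dtype=float)[:, self.selected])
        return self.y_scaler.invert(self.net.predict(Xs))


class DoubleCVEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Double cross-validation trainer producing a guarded prediction ensemble.

    Fitting runs the full NR×NO×NI scheme on a descriptor count matrix that
    has already passed the global filters (rare-fragment support and
    variance).  Local descriptor selection runs per outer fold (on the
    outer-training rows) by default, or per inner member; scalers are always
    fitted on each member's inner-training rows only.

    Fitted attributes: ``members_`` (the ensemble), ``cv_result_`` (the
    consolidated CVResult), ``fold_plan_``.
    """

    def __init__(
        self,
        NO: int = 5,
        NI: int = 4,
        NR: int = 1,
        n_selected: int = 200,
        selection_method: str = "stepwise_pls",
        selection_scope: str = "outer",
        scaler_method: str = "range01",
        hidden_ratios: tuple[float, ...] = (0.3,),
        dropout_p: float = 0.0,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 1000,
        patience: int = 20,
        min_success_fraction: float = 0.8,
        seed: int = 0,
    ):
        self.NO = NO
        self.NI = NI
        self.NR = NR
        self.n_selected = n_selected
        self.selection_method = selection_method
        self.selection_scope = selection_scope
        self.scaler_method = scaler_method
        self.hidden_ratios = hidden_ratios
        self.dropout_p = dropout_p
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_success_fraction = min_success_fraction
        self.seed = seed

    def fit(self, X, y):
        if self.selection_scope not in ("outer", "inner"):
            raise ValueError("selection_scope must be 'outer' or 'inner'")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        spec = DCVSpec(self.NO, self.NI, self.NR, self.seed)
        plan = make_fold_plan(n, spec)
        scaler_spec = ScalerSpec(self.scaler_method)
        members: list[EnsembleMember] = []
        predictions = np.full((self.NR, n), np.nan)
        n_failed = 0
        member_seed = self.seed

        for r in range(self.NR):
            for o, outer_fold in enumerate(plan.outer[r]):
                outer_train = np.setdiff1d(np.arange(n), outer_fold)
                if self.selection_scope == "outer":
                    sel = run_selection(
                        X[outer_train], y[outer_train], self.n_selected,
                        self.selection_method, seed=self.seed + 1000 * r + o,
                    )
                    sel_idx = np.asarray(sel.selected_indices, dtype=int)
                fold_preds = []
                for i, inner_fold in enumerate(plan.inner[r][o]):
                    member_seed += 1
                    train_rows = np.setdiff1d(outer_train, inner_fold)
                    if self.selection_scope == "inner":
                        sel = run_selection(
                            X[train_rows], y[train_rows], self.n_selected,
                            self.selection_method, seed=member_seed,
                        )
                        sel_idx = np.asarray(sel.selected_indices, dtype=int)
                    try:
                        member = self._fit_member(
                            X, y, train_rows, inner_fold, outer_fold, sel_idx,
                            scaler_spec, (r, o, i), member_seed,
                        )
                        fold_preds.append(member.predict_raw(X[outer_fold]))
                        members.append(member)
                    except FloatingPointError as exc:
                        n_failed += 1
                        logger.warning(
                            "member (rep %d, outer %d, inner %d) failed: %s",
                            r, o, i, exc,
                        )
                if not fold_preds:
                    raise RuntimeError(
                        f"all inner members of rep {r} outer fold {o} failed"
                    )
                predictions[r, outer_fold] = np.mean(fold_preds, axis=0)

        total = self.NR * self.NO * self.NI
        if total - n_failed < self.min_success_fraction * total:
            raise RuntimeError(
                f"only {total - n_failed}/{total} ensemble members trained"
            )
        self.members_ = members
        self.fold_plan_ = plan
        self.cv_result_ = consolidate(predictions, y)
        self.n_features_in_ = X.shape[1]
        self.endpoint_range_ = (float(y.min()), float(y.max()))
        return self

    def _fit_member(self, X, y, train_rows, stop_rows, valid_rows, sel_idx,
                    scaler_spec, provenance, seed) -> EnsembleMember:
        x_scaler = FittedScaler.fit(X[np.ix_(train_rows, sel_idx)],
                                    scaler_spec, seed)
        y_scaler = FittedScaler.fit(y[train_rows], scaler_spec, seed)
        net = SELUNetRegressor(
            hidden_ratios=tuple(self.hidden_ratios),
            dropout_p=self.dropout_p,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=seed,
        )
        net.fit(
            x_scaler.apply(X[np.ix_(train_rows, sel_idx)]),
            y_scaler.apply(y[train_rows]),
            stop_set=(
                x_scaler.apply(X[np.ix_(stop_rows, sel_idx)]),
                y_scaler.apply(y[stop_rows]),
            ),
        )
        return EnsembleMember(
            net=net,
            x_scaler=x_scaler,
            y_scaler=y_scaler,
            selected=sel_idx,
            provenance=provenance,
            train_rows=train_rows,
            valid_rows=np.asarray(valid_rows, dtype=int),
            ok=True,
        )

    def member_predictions(self, X) -> np.ndarray:
        """Raw per-member predictions on the original endpoint scale,
        shape (n_members, n_rows)."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        return np.vstack([m.predict_raw(X) for m in self.members_])

    def predict(self, X) -> np.ndarray:
        """Plain ensemble mean; the guarded protocol lives in the predictor
        module."""
        return self.member_predictions(X).mean(axis=0)


def run_double_cv(
    X: np.ndarray,
    y: np.ndarray,
    dcv_spec: DCVSpec = DCVSpec(),
    **estimator_kwargs,
) -> tuple[DoubleCVEnsembleRegressor, CVResult]:
    """Functional wrapper: fit the double-CV ensemble and return it with its
    consolidated CVResult."""
    est = DoubleCVEnsembleRegressor(
        NO=dcv_spec.NO, NI=dcv_spec.NI, NR=dcv_spec.NR, seed=dcv_spec.seed,
        **estimator_kwargs,
    )
    est.fit(X, y)
    return est, est.cv_result_
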