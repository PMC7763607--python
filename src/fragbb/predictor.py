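"""Guarded ensemble prediction and gradient-based fragment contributions.

The guarded protocol turns the double-CV ensemble into an
applicability-controlled predictor.  For one compound:

1. every ensemble member predicts and the value is transformed back to the
   LogBB scale;
2. values outside the sanity range (default [−2.5, 2.5], wider than the
   training span) are discarded — they signal that the compound is likely
   beyond the member's applicability domain;
3. if strictly more than ``max_fail_fraction`` of the members were
   discarded, a prediction failure is reported;
4. the surviving values are clipped to the acceptable range
   (default [−2, 2]);
5. their mean and (population) standard deviation are computed;
6. if the standard deviation strictly exceeds ``max_sd_fraction`` of the
   acceptable-range width, a prediction failure is reported;
7. otherwise mean and standard deviation are reported.

Fragment contributions: per compound and member, the analytic gradient of
the scaled output with respect to the scaled inputs is multiplied by the
scaled inputs; products are averaged over members, and optionally over a
compound set, giving the average influence of each fragment on the
predicted permeability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .doublecv import DoubleCVEnsembleRegressor


@dataclass(frozen=True)
class PredictionConfig:
    """Thresholds of the guarded prediction protocol."""

    sanity_range: tuple[float, float] = (-2.5, 2.5)
    clip_range: tuple[float, float] = (-2.0, 2.0)
    max_fail_fraction: float = 0.5
    max_sd_fraction: float = 0.3

    def __post_init__(self):
        if not (self.sanity_range[0] <= self.clip_range[0]
                and self.clip_range[1] <= self.sanity_range[1]):
            raise ValueError("clip_range must lie within sanity_range")
        for frac in (self.max_fail_fraction, self.max_sd_fraction):
            if not 0 < frac < 1:
                raise ValueError("fractions must be in (0, 1)")

    @property
    def sd_threshold(self) -> float:
        return self.max_sd_fraction * (self.clip_range[1] - self.clip_range[0])


@dataclass
class PredictionResult:
    """Guarded prediction output for one compound."""

    id: str
    status: str  # ok | failure
    mean: float = math.nan
    sd: float = math.nan
    n_valid: int = 0
    failure_reason: str = "none"  # none | too_many_out_of_range | sd_too_large
    #               | featurization_failure


def guarded_predict(
    member_values: np.ndarray,
    config: PredictionConfig = PredictionConfig(),
    compound_id: str = "",
    n_failed_extra: int = 0,
) -> PredictionResult:
    """Apply the guarded protocol to raw per-member predicted values.

    ``n_failed_extra`` counts members that failed before producing a value
    (e.g. featurization failures); they enter the fail fraction.
    """
    values = np.asarray(member_values, dtype=float).ravel()
    n_total = values.size + n_failed_extra
    lo, hi = config.sanity_range
    survivors = values[(values >= lo) & (values <= hi) & np.isfinite(values)]
    n_failed = n_total - survivors.size
    # strict inequality: failure only when MORE than the allowed fraction fail
    if n_failed > config.max_fail_fraction * n_total:
        return PredictionResult(compound_id, "failure",
                                n_valid=survivors.size,
                                failure_reason="too_many_out_of_range")
    clipped = np.clip(survivors, *config.clip_range)
    mean = float(clipped.mean())
    sd = float(clipped.std())  # population SD: ensemble spread descriptor
    if sd > config.sd_threshold:
        return PredictionResult(compound_id, "failure", mean=mean, sd=sd,
                                n_valid=survivors.size,
                                failure_reason="sd_too_large")
    return PredictionResult(compound_id, "ok", mean=mean, sd=sd,
                            n_valid=survivors.size)


def predict_one(
    ensemble: DoubleCVEnsembleRegressor,
    features: np.ndarray,
    config: PredictionConfig = PredictionConfig(),
    compound_id: str = "",
) -> PredictionResult:
    """Guarded prediction for one compound's full feature vector."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    try:
        values = ensemble.member_predictions(features)[:, 0]
    except Exception:
        return PredictionResult(compound_id, "failure",
                                failure_reason="featurization_failure")
    return guarded_predict(values, config, compound_id)


def predict_batch(
    ensemble: DoubleCVEnsembleRegressor,
    features: np.ndarray,
    config: PredictionConfig = PredictionConfig(),
    ids: Sequence[str] | None = None,
    experimental: np.ndarray | None = None,
) -> tuple[list[PredictionResult], dict]:
    """Guarded predictions for a compound table, with validation statistics.

    When experimental values are given, the summary reports N (successful
    predictions with an experimental value), Pearson R, RMSE, the counts of
    absolute errors above 1.0 and 1.5 log units, and the correlation
    between the ensemble SD and the absolute error (the SD-as-applicability
    diagnostic).  A degenerate (constant) prediction vector yields R = NaN
    with ``r_defined`` False.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    all_values = ensemble.member_predictions(features)
    results = [
        guarded_predict(all_values[:, i], config, ids[i]) for i in range(n)
    ]
    summary: dict = {
        "n_total": n,
        "n_ok": sum(r.status == "ok" for r in results),
        "n_failure": sum(r.status == "failure" for r in results),
    }
    if experimental is not None:
        experimental = np.asarray(experimental, dtype=float).ravel()
        ok = np.array([
            r.status == "ok" and np.isfinite(experimental[i])
            for i, r in enumerate(results)
        ])
        pred = np.array([r.mean for r in results])[ok]
        sd = np.array([r.sd for r in results])[ok]
        exp = experimental[ok]
        err = pred - exp
        summary["N"] = int(ok.sum())
        summary["RMSE"] = float(np.sqrt(np.mean(err**2))) if ok.any() else math.nan
        r_defined = ok.sum() >= 2 and pred.std() > 0 and exp.std() > 0
        summary["R"] = (
            float(np.corrcoef(pred, exp)[0, 1]) if r_defined else math.nan
        )
        summary["r_defined"] = bool(r_defined)
        summary["n_abs_error_gt_1.0"] = int(np.sum(np.abs(err) > 1.0))
        summary["n_abs_error_gt_1.5"] = int(np.sum(np.abs(err) > 1.5))
        sd_ok = ok.sum() >= 2 and sd.std() > 0 and np.abs(err).std() > 0
        summary["sd_error_correlation"] = (
            float(np.corrcoef(sd, np.abs(err))[0, 1]) if sd_ok else math.nan
        )
    return results, summary


@dataclass
class ContributionReport:
    """Fragment contributions: per-compound values and set averages."""

    fragment_keys: list[str]
    per_compound: np.ndarray  # (n_compounds, n_fragments)
    average: np.ndarray  # (n_fragments,)

    def ranked(self) -> pd.DataFrame:
        """Fragments ordered from most negative to most positive average
        contribution."""
        df = pd.DataFrame({
            "fragment": self.fragment_keys,
            "mean_contribution": self.average,
            "sd_over_compounds": self.per_compound.std(axis=0),
        })
        return df.sort_values(
            "mean_contribution", kind="stable"
        ).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.ranked().to_csv(path, index=False)


def fragment_contributions(
    ensemble: DoubleCVEnsembleRegressor,
    features: np.ndarray,
    fragment_keys: Sequence[str] | None = None,
) -> ContributionReport:
    """Average gradient × scaled-input fragment contributions.

    For each compound and ensemble member, the gradient of the scaled
    output with respect to the member's scaled inputs is multiplied
    elementwise by those scaled inputs; the products are mapped back to the
    full fragment catalog (a fragment outside a member's selected subset
    contributes 0 for that member) and averaged over members.  The report
    also carries the average over the compound set.
    """
    features = np.asarray(features, dtype=float)
    n, p = features.shape
    if fragment_keys is None:
        fragment_keys = [f"f{j}" for j in range(p)]
    total = np.zeros((n, p))
    for member in ensemble.members_:
        Xs = member.x_scaler.apply(features[:, member.selected])
        grad = member.net.gradient_input(Xs)
        total[:, member.selected] += grad * Xs
    per_compound = total / len(ensemble.members_)
    return ContributionReport(
        fragment_keys=list(fragment_keys),
        per_compound=per_compound,
        average=per_compound.mean(axis=0),
    )
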