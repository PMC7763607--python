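"""Hyperparameter search over the double cross-validation workflow.

Each trial draws a hyperparameter configuration (fragment size cap, number
of selected descriptors, hidden-layer ratio, dropout probability,
selection and scaling methods), runs a full double-CV evaluation, and is
scored by

    Loss = −Q² + log(Time) / 100          (Time in seconds, Time ≥ 1)

so that better predictivity always wins and, at equal predictivity, the
faster configuration wins.  The log base defaults to natural and is
configurable.  Trials that fail or exceed the time limit are discarded.
Configurations are drawn by seeded uniform random search; the trial log is
append-only JSON-lines and replayable from the recorded seeds.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np

from .doublecv import DCVSpec, run_double_cv


def loss_function(q2: float, time_seconds: float, log_base: float = math.e) -> float:
    """Search loss: −Q² + log(Time)/100, decreasing in Q², increasing in time."""
    if time_seconds <= 0:
        raise ValueError("time must be positive")
    return -q2 + math.log(time_seconds, log_base) / 100.0


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter ranges explored by the search."""

    max_fragment_atoms: tuple[int, ...] = (6, 8, 10)
    n_selected: tuple[int, int] = (100, 1000)
    hidden_ratio: tuple[float, float] = (0.2, 0.6)
    dropout_p: tuple[float, float] = (0.0, 0.5)
    selection_methods: tuple[str, ...] = ("stepwise_pls",)
    scaler_methods: tuple[str, ...] = ("range01",)

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "max_fragment_atoms": int(rng.choice(self.max_fragment_atoms)),
            "n_selected": int(rng.integers(self.n_selected[0],
                                           self.n_selected[1] + 1)),
            "hidden_ratio": float(rng.uniform(*self.hidden_ratio)),
            "dropout_p": float(rng.uniform(*self.dropout_p)),
            "selection_method": str(rng.choice(self.selection_methods)),
            "scaler_method": str(rng.choice(self.scaler_methods)),
        }


@dataclass
class TrialRecord:
    """One evaluated configuration."""

    trial: int
    seed: int
    hyperparameters: dict
    Q2: float = math.nan
    Time: float = math.nan
    Loss: float = math.nan
    status: str = "ok"  # ok | discarded
    detail: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def run_search(
    space: SearchSpace,
    budget: int,
    X: np.ndarray,
    y: np.ndarray,
    dcv_spec: DCVSpec = DCVSpec(),
    time_limit: float = math.inf,
    log_base: float = math.e,
    seed: int = 0,
    time_fn: Callable[[dict, float], float] | None = None,
    log_path=None,
    **fixed_kwargs,
) -> tuple[TrialRecord, list[TrialRecord]]:
    """Random search over ``budget`` double-CV evaluations.

    ``time_fn(hyperparameters, wall_seconds) -> seconds`` lets tests inject
    a deterministic time measurement; by default wall-clock time of the
    double-CV run is used (floored at 1 s so the log term is defined).
    Returns the minimum-loss successful trial and the full log.  The
    feature matrix is expected pre-featurized at the largest fragment size;
    ``max_fragment_atoms`` is recorded but acts through ``feature_sets`` if
    a mapping {max_atoms: X} is passed instead of a single matrix.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    feature_sets = X if isinstance(X, dict) else None
    log: list[TrialRecord] = []
    best: TrialRecord | None = None
    for trial in range(budget):
        trial_seed = int(rng.integers(0, 2**31 - 1))
        params = SearchSpace.sample(space, np.random.default_rng(trial_seed))
        record = TrialRecord(trial=trial, seed=trial_seed,
                             hyperparameters=params)
        X_trial = (
            feature_sets[params["max_fragment_atoms"]]
            if feature_sets is not None else X
        )
        n_cols = np.asarray(X_trial).shape[1]
        t0 = time.perf_counter()
        try:
            _, cv = run_double_cv(
                X_trial, y,
                DCVSpec(dcv_spec.NO, dcv_spec.NI, dcv_spec.NR, trial_seed),
                n_selected=min(params["n_selected"], n_cols),
                selection_method=params["selection_method"],
                scaler_method=params["scaler_method"],
                hidden_ratios=(params["hidden_ratio"],),
                dropout_p=params["dropout_p"],
                **fixed_kwargs,
            )
            wall = time.perf_counter() - t0
            seconds = max(1.0, time_fn(params, wall) if time_fn else wall)
            if seconds > time_limit:
                record.status = "discarded"
                record.detail = "time limit exceeded"
            else:
                record.Q2 = cv.Q2
                record.Time = seconds
                record.Loss = loss_function(cv.Q2, seconds, log_base)
        except Exception as exc:
            record.status = "discarded"
            record.detail = str(exc)
        log.append(record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(record.to_json() + "\n")
        if record.status == "ok" and (best is None or record.Loss < best.Loss):
            best = record
    if best is None:
        raise RuntimeError("all trials were discarded")
    return best, log
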