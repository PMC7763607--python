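"""End-to-end pipeline: curation, training, prediction, validation, CLI.

The training pipeline chains the stages on a curated compound table:
fragment featurization with the rare-fragment support filter (global),
scaled-variance filtering (global), then the repeated double
cross-validation ensemble with local descriptor selection.  Prediction
and interpretation run the fitted bundle through the guarded protocol and
the gradient-based contribution analysis.  External validation reports
the comparison statistics (N, R, RMSE, large-error counts, ensemble-SD
vs error correlation) stratified by overlap with the training set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import click
import joblib
import numpy as np
import pandas as pd
import yaml

from .doublecv import CVResult, DoubleCVEnsembleRegressor
from .fragments import FragmentFeaturizer
from .hypersearch import SearchSpace, run_search
from .molgraph import (
    CompoundRecord,
    canonical_structure_key,
    parse_structure,
    read_sdf,
    read_smiles_csv,
)
from .predictor import (
    PredictionConfig,
    fragment_contributions,
    predict_batch,
)
from .preprocess import FittedScaler, ScalerSpec, variance_filter
from .synthdata import SyntheticSpec, generate_dataset, write_dataset_csv

logger = logging.getLogger(__name__)

ORGANIC_ELEMENT = "C"  # a molecule without carbon is treated as inorganic
DUPLICATE_SPREAD_LIMIT = 0.3  # log units; the experimental LogBB error scale


@dataclass(frozen=True)
class CurationConfig:
    """Dataset curation rules."""

    endpoint_range: tuple[float, float] = (-2.5, 2.5)
    duplicate_spread_limit: float = DUPLICATE_SPREAD_LIMIT
    require_carbon: bool = True


def curate(
    table: pd.DataFrame,
    config: CurationConfig = CurationConfig(),
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Curate a compound table into modeling records plus a rejects report.

    Rules: drop unparseable structures, records without a finite endpoint,
    endpoints outside the allowed range (unrealistic values), and
    carbon-free (inorganic) molecules.  Structural duplicates (by canonical
    structure key) are merged to their mean endpoint when their spread is
    within the experimental-error scale, otherwise all conflicting records
    are rejected.  Every input row lands exactly once in kept or rejects.
    """
    rejects: list[dict] = []
    parsed: list[tuple[str, CompoundRecord]] = []
    for _, row in table.iterrows():
        cid = str(row.get("id", ""))
        smi = str(row.get("smiles", ""))
        raw = row.get("logbb")
        try:
            value = float(raw)
        except (TypeError, ValueError):
            value = math.nan
        if not math.isfinite(value):
            rejects.append({"id": cid, "reason": "missing_endpoint"})
            continue
        if not config.endpoint_range[0] <= value <= config.endpoint_range[1]:
            rejects.append({"id": cid, "reason": "out_of_range", "logbb": value})
            continue
        try:
            graph = parse_structure(smi, "smiles", cid)
        except Exception as exc:
            rejects.append({"id": cid, "reason": "parse_failure",
                            "detail": str(exc)})
            continue
        if config.require_carbon and not any(
            a.element == ORGANIC_ELEMENT for a in graph.atoms
        ):
            rejects.append({"id": cid, "reason": "inorganic"})
            continue
        key = canonical_structure_key(graph)
        parsed.append((key, CompoundRecord(cid, graph, value, smiles=smi)))

    kept: list[CompoundRecord] = []
    by_key: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for key, rec in parsed:
        if key not in by_key:
            order.append(key)
        by_key.setdefault(key, []).append(rec)
    for key in order:
        group = by_key[key]
        if len(group) == 1:
            kept.append(group[0])
            continue
        values = [r.logbb for r in group]
        if max(values) - min(values) <= config.duplicate_spread_limit:
            first = group[0]
            kept.append(CompoundRecord(
                first.id, first.graph, float(np.mean(values)),
                smiles=first.smiles,
            ))
            for r in group[1:]:
                rejects.append({"id": r.id, "reason": "duplicate_merged",
                                "merged_into": first.id})
        else:
            for r in group:
                rejects.append({"id": r.id, "reason": "conflicting_duplicates",
                                "logbb": r.logbb})
    return kept, pd.DataFrame(
        rejects, columns=["id", "reason", "logbb", "detail", "merged_into"]
    )


def find_overlap(
    set_a: Sequence[CompoundRecord], set_b: Sequence[CompoundRecord]
) -> tuple[list[str], list[str]]:
    """Split set_a ids into (overlapping-with-b, non-overlapping), by
    canonical structure key."""
    keys_b = {canonical_structure_key(r.graph) for r in set_b}
    overlap, non_overlap = [], []
    for rec in set_a:
        (overlap if canonical_structure_key(rec.graph) in keys_b
         else non_overlap).append(rec.id)
    return overlap, non_overlap


@dataclass
class ModelBundle:
    """A trained pipeline: featurizer, global column filter, ensemble."""

    featurizer: FragmentFeaturizer
    kept_columns: np.ndarray
    ensemble: DoubleCVEnsembleRegressor
    cv_result: CVResult
    config: dict = field(default_factory=dict)

    def featurize(self, records: Sequence[CompoundRecord]) -> np.ndarray:
        return self.featurizer.transform(records)[:, self.kept_columns]

    @property
    def fragment_keys(self) -> list[str]:
        return [self.featurizer.catalog_[i] for i in self.kept_columns]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        return joblib.load(path)


def fit_pipeline(
    records: Sequence[CompoundRecord],
    max_atoms: int = 8,
    levels: tuple[int, ...] = (1, 2, 3),
    min_support: int = 5,
    variance_threshold: float = 1e-6,
    **ensemble_kwargs,
) -> ModelBundle:
    """Featurize, apply the global filters, and train the double-CV ensemble."""
    y = np.array([r.logbb for r in records], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("all training records need finite LogBB values")
    featurizer = FragmentFeaturizer(max_atoms, levels, min_support).fit(records)
    X_all = featurizer.transform(records)
    # global variance filter on [0,1]-scaled columns
    scaled = FittedScaler.fit(X_all, ScalerSpec("range01")).apply(X_all)
    kept = variance_filter(scaled, variance_threshold)
    X = X_all[:, kept]
    ensemble = DoubleCVEnsembleRegressor(**ensemble_kwargs)
    ensemble.fit(X, y)
    return ModelBundle(
        featurizer=featurizer,
        kept_columns=kept,
        ensemble=ensemble,
        cv_result=ensemble.cv_result_,
        config={"max_atoms": max_atoms, "levels": levels,
                "min_support": min_support,
                "variance_threshold": variance_threshold,
                **ensemble_kwargs},
    )


def validate_external(
    bundle: ModelBundle,
    external: Sequence[CompoundRecord],
    train_records: Sequence[CompoundRecord] | None = None,
    config: PredictionConfig = PredictionConfig(),
) -> dict:
    """External validation report with overlap stratification.

    Returns a dict with full-set and (when training records are given)
    overlap/non-overlap statistics, plus an outlier table of compounds
    with absolute errors above 1.0 log units.
    """
    if not external:
        return {"full": {"n_total": 0}, "outliers": []}
    X = bundle.featurize(external)
    exp = np.array(
        [r.logbb if r.logbb is not None else math.nan for r in external]
    )
    ids = [r.id for r in external]
    results, summary = predict_batch(bundle.ensemble, X, config, ids, exp)
    report: dict = {"full": summary}
    train_by_key: dict[str, float] = {}
    if train_records is not None:
        train_by_key = {
            canonical_structure_key(r.graph): r.logbb for r in train_records
        }
        overlap_mask = np.array([
            canonical_structure_key(r.graph) in train_by_key for r in external
        ])
        for name, mask in (("overlapping", overlap_mask),
                           ("non_overlapping", ~overlap_mask)):
            sub = [i for i in range(len(external)) if mask[i]]
            if sub:
                _, s = predict_batch(
                    bundle.ensemble, X[sub], config,
                    [ids[i] for i in sub], exp[sub],
                )
            else:
                s = {"n_total": 0}
            report[name] = s
    outliers = []
    for i, res in enumerate(results):
        if res.status != "ok" or not math.isfinite(exp[i]):
            continue
        if abs(res.mean - exp[i]) > 1.0:
            entry = {"id": res.id, "logbb_validation": float(exp[i]),
                     "logbb_predicted": res.mean}
            if train_records is not None:
                key = canonical_structure_key(external[i].graph)
                if key in train_by_key:
                    entry["logbb_training"] = train_by_key[key]
            outliers.append(entry)
    report["outliers"] = outliers
    return report


@dataclass
class RunManifest:
    """Replayable record of a training run."""

    config: dict
    seed: int
    software_version: str
    dataset_fingerprint: str
    artifacts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def dataset_fingerprint(records: Sequence[CompoundRecord]) -> str:
    """Order-insensitive fingerprint of structures + endpoints."""
    import hashlib

    items = sorted(
        f"{canonical_structure_key(r.graph)}:{r.logbb}" for r in records
    )
    return hashlib.sha256("\n".join(items).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# command-line interface

def _load_records(path: str) -> list[CompoundRecord]:
    if path.endswith(".sdf"):
        records, rejects = read_sdf(path)
    else:
        records, rejects = read_smiles_csv(path)
    for rej in rejects:
        logger.warning("rejected input %s: %s", rej.get("id"), rej.get("reason"))
    return records


@click.group()
def cli():
    """Fragment-descriptor LogBB modeling workflow."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


@cli.command()
@click.argument("input_csv")
@click.option("--out", required=True, help="descriptor matrix TSV")
@click.option("--max-atoms", default=8, show_default=True)
@click.option("--min-support", default=5, show_default=True)
def featurize(input_csv, out, max_atoms, min_support):
    """Build the fragment descriptor matrix for a compound table."""
    from .fragments import build_matrix, filter_rare

    records = _load_records(input_csv)
    matrix, rejects = build_matrix(records, max_atoms)
    matrix = filter_rare(matrix, min_support)
    matrix.to_tsv(out)
    click.echo(f"{matrix.shape[0]} compounds x {matrix.shape[1]} fragments")
    if rejects:
        pd.DataFrame(rejects).to_csv(Path(out).with_suffix(".rejects.csv"),
                                     index=False)


@cli.command()
@click.argument("input_csv")
@click.option("--out", required=True, help="model bundle path (.joblib)")
@click.option("--summary", default=None, help="summary JSON path")
@click.option("--max-atoms", default=8, show_default=True)
@click.option("--n-selected", default=200, show_default=True)
@click.option("--no", "n_outer", default=5, show_default=True)
@click.option("--ni", "n_inner", default=4, show_default=True)
@click.option("--nr", "n_rep", default=1, show_default=True)
@click.option("--hidden-ratio", default=0.3, show_default=True)
@click.option("--dropout-p", default=0.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
def train(input_csv, out, summary, max_atoms, n_selected, n_outer, n_inner,
          n_rep, hidden_ratio, dropout_p, seed):
    """Curate, featurize and train the double-CV ensemble."""
    table = pd.read_csv(input_csv)
    records, rejects = curate(table)
    click.echo(f"curated: {len(records)} kept, {len(rejects)} rejected")
    t0 = time.perf_counter()
    bundle = fit_pipeline(
        records, max_atoms=max_atoms, n_selected=n_selected,
        NO=n_outer, NI=n_inner, NR=n_rep,
        hidden_ratios=(hidden_ratio,), dropout_p=dropout_p, seed=seed,
    )
    bundle.save(out)
    stats = bundle.cv_result.summary()
    stats["wall_seconds"] = round(time.perf_counter() - t0, 1)
    manifest = RunManifest(
        config=bundle.config, seed=seed, software_version=_version(),
        dataset_fingerprint=dataset_fingerprint(records),
        artifacts={"bundle": str(out)},
    )
    click.echo(json.dumps(stats, indent=2))
    if summary:
        with open(summary, "w") as fh:
            json.dump({"cv": stats, "manifest": json.loads(manifest.to_json())},
                      fh, indent=2)


@cli.command()
@click.argument("model_path")
@click.argument("input_csv")
@click.option("--out", required=True, help="predictions CSV")
def predict(model_path, input_csv, out):
    """Guarded ensemble prediction for a compound table."""
    bundle = ModelBundle.load(model_path)
    records = _load_records(input_csv)
    X = bundle.featurize(records)
    results, summary = predict_batch(
        bundle.ensemble, X, ids=[r.id for r in records]
    )
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(out,
                                                                  index=False)
    click.echo(json.dumps(summary, indent=2))


@cli.command()
@click.argument("model_path")
@click.argument("input_csv")
@click.option("--out", required=True, help="contribution report CSV")
def interpret(model_path, input_csv, out):
    """Fragment-contribution analysis over a compound set."""
    bundle = ModelBundle.load(model_path)
    records = _load_records(input_csv)
    X = bundle.featurize(records)
    report = fragment_contributions(bundle.ensemble, X, bundle.fragment_keys)
    report.to_csv(out)
    click.echo(f"wrote contributions for {len(report.fragment_keys)} fragments")


@cli.command()
@click.argument("model_path")
@click.argument("external_csv")
@click.option("--train-csv", default=None,
              help="training table for overlap stratification")
@click.option("--out", required=True, help="validation report JSON")
def validate(model_path, external_csv, train_csv, out):
    """External validation with overlap-stratified statistics."""
    bundle = ModelBundle.load(model_path)
    external = _load_records(external_csv)
    # only the unrealistic-endpoint exclusion is applied to external data
    lo, hi = (-2.5, 2.5)
    external = [r for r in external
                if r.logbb is None or lo <= r.logbb <= hi]
    train_records = _load_records(train_csv) if train_csv else None
    report = validate_external(bundle, external, train_records)
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    click.echo(json.dumps(report.get("full", {}), indent=2, default=float))


@cli.command("hypersearch")
@click.argument("input_csv")
@click.option("--budget", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--config", "config_path", default=None,
              help="YAML search-space overrides")
@click.option("--log", "log_path", default=None, help="trial log JSONL")
def hypersearch_cmd(input_csv, budget, seed, config_path, log_path):
    """Random hyperparameter search over double-CV evaluations."""
    table = pd.read_csv(input_csv)
    records, _ = curate(table)
    overrides = {}
    if config_path:
        with open(config_path) as fh:
            overrides = yaml.safe_load(fh) or {}
    space_kwargs = {
        k: tuple(v) for k, v in overrides.get("space", {}).items()
    }
    space = SearchSpace(**space_kwargs)
    y = np.array([r.logbb for r in records])
    feature_sets = {}
    for ma in space.max_fragment_atoms:
        featurizer = FragmentFeaturizer(max_atoms=ma).fit(records)
        X_all = featurizer.transform(records)
        scaled = FittedScaler.fit(X_all, ScalerSpec("range01")).apply(X_all)
        feature_sets[ma] = X_all[:, variance_filter(scaled)]
    best, log = run_search(
        space, budget, feature_sets, y, seed=seed, log_path=log_path,
        **overrides.get("fixed", {}),
    )
    click.echo(best.to_json())


@cli.command()
@click.option("--out", required=True, help="dataset CSV")
@click.option("--truth", default=None, help="ground-truth sidecar CSV")
@click.option("--n", default=500, show_default=True)
@click.option("--noise-sd", default=0.3, show_default=True)
@click.option("--seed", default=0, show_default=True)
def synth(out, truth, n, noise_sd, seed):
    """Generate a synthetic dataset with planted fragment effects."""
    spec = SyntheticSpec(n_compounds=n, noise_sd=noise_sd, seed=seed)
    records, coefficients = generate_dataset(spec)
    write_dataset_csv(records, out, coefficients, truth)
    click.echo(f"wrote {len(records)} compounds to {out}")


def _version() -> str:
    from . import __version__

    return __version__
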