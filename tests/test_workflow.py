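"""Curation, overlap analysis, external validation and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fragbb.molgraph import CompoundRecord, parse_structure
from fragbb.synthdata import SyntheticSpec, generate_dataset, write_dataset_csv
from fragbb.workflow import (
    CurationConfig,
    ModelBundle,
    cli,
    curate,
    dataset_fingerprint,
    find_overlap,
    fit_pipeline,
    validate_external,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["id", "smiles", "logbb"])


class TestCurate:
    def test_unrealistic_endpoint_rejected(self):
        kept, rejects = curate(_table([("a", "CCO", -3.0)]))
        assert kept == []
        assert rejects.iloc[0]["reason"] == "out_of_range"

    def test_close_duplicates_merged_to_mean(self):
        kept, rejects = curate(
            _table([("a", "CCO", 0.10), ("b", "OCC", 0.12)])
        )
        assert len(kept) == 1
        assert kept[0].logbb == pytest.approx(0.11)
        assert (rejects["reason"] == "duplicate_merged").sum() == 1

    def test_conflicting_duplicates_both_rejected(self):
        kept, rejects = curate(
            _table([("a", "CCO", 0.10), ("b", "OCC", 0.80)])
        )
        assert kept == []
        assert (rejects["reason"] == "conflicting_duplicates").sum() == 2

    def test_inorganic_rejected(self):
        kept, rejects = curate(_table([("salt", "[Na+].[Cl-]", 0.0)]))
        assert kept == []
        assert rejects.iloc[0]["reason"] == "inorganic"

    def test_unparseable_rejected(self):
        kept, rejects = curate(_table([("bad", "xx((", 0.0)]))
        assert rejects.iloc[0]["reason"] == "parse_failure"

    def test_missing_endpoint_rejected(self):
        kept, rejects = curate(_table([("a", "CCO", None)]))
        assert rejects.iloc[0]["reason"] == "missing_endpoint"

    def test_row_accounting(self):
        table = _table([
            ("a", "CCO", 0.1), ("b", "OCC", 0.12), ("c", "CCN", -3.0),
            ("d", "c1ccccc1", 0.5), ("e", "bad((", 0.0),
        ])
        kept, rejects = curate(table)
        assert len(kept) + len(rejects) == len(table)

    def test_idempotence(self):
        table = _table([
            ("a", "CCO", 0.1), ("b", "OCC", 0.12), ("c", "CCN", 0.4),
        ])
        kept1, _ = curate(table)
        table2 = pd.DataFrame(
            [(r.id, r.smiles, r.logbb) for r in kept1],
            columns=["id", "smiles", "logbb"],
        )
        kept2, rejects2 = curate(table2)
        assert len(rejects2) == 0
        assert [(r.id, r.logbb) for r in kept2] == [
            (r.id, r.logbb) for r in kept1
        ]

    def test_boundary_endpoint_kept(self):
        kept, _ = curate(_table([("a", "CCO", -2.5)]))
        assert len(kept) == 1


class TestFindOverlap:
    def _rec(self, rid, smiles):
        return CompoundRecord(rid, parse_structure(smiles))

    def test_identical_single_compound(self):
        a = [self._rec("x", "CCO")]
        b = [self._rec("y", "OCC")]
        overlap, non = find_overlap(a, b)
        assert overlap == ["x"] and non == []

    def test_disjoint_sets(self):
        a = [self._rec("x", "CCO")]
        b = [self._rec("y", "CCN")]
        overlap, non = find_overlap(a, b)
        assert overlap == [] and non == ["x"]

    def test_cross_format_overlap(self):
        from rdkit import Chem

        block = Chem.MolToMolBlock(Chem.MolFromSmiles("c1ccccc1"))
        a = [CompoundRecord("sdf", parse_structure(block, "sdf"))]
        b = [self._rec("smi", "c1ccccc1")]
        overlap, _ = find_overlap(a, b)
        assert overlap == ["sdf"]


@pytest.fixture(scope="module")
def trained_bundle():
    records, coefs = generate_dataset(
        SyntheticSpec(n_compounds=150, noise_sd=0.1, seed=21)
    )
    bundle = fit_pipeline(
        records, max_atoms=4, n_selected=15, NO=3, NI=2, seed=0,
        max_epochs=400,
    )
    return bundle, records, coefs


class TestPipelineAndValidation:
    def test_bundle_save_load_round_trip(self, trained_bundle, tmp_path):
        bundle, records, _ = trained_bundle
        path = tmp_path / "model.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        X = bundle.featurize(records[:5])
        assert np.allclose(
            loaded.ensemble.predict(X), bundle.ensemble.predict(X)
        )

    def test_self_validation_small_errors(self, trained_bundle):
        """Validating a well-fit model against its own training set yields
        a small RMSE and no extreme outliers."""
        bundle, records, _ = trained_bundle
        report = validate_external(bundle, records, train_records=records)
        assert report["full"]["RMSE"] < 0.5
        assert report["full"]["n_abs_error_gt_1.5"] == 0
        assert report["non_overlapping"]["n_total"] == 0

    def test_degenerate_model_r_near_zero(self, trained_bundle, rng):
        """A model predicting a constant has undefined R on externals."""
        bundle, records, _ = trained_bundle
        from fragbb.predictor import predict_batch

        X = bundle.featurize(records[:30])
        # constant experimental values -> correlation undefined
        _, summary = predict_batch(
            bundle.ensemble, X, experimental=np.zeros(30)
        )
        assert not summary["r_defined"]

    def test_empty_external_table(self, trained_bundle):
        bundle, _, _ = trained_bundle
        report = validate_external(bundle, [])
        assert report["full"]["n_total"] == 0
        assert report["outliers"] == []

    def test_fingerprint_order_invariant(self, trained_bundle):
        _, records, _ = trained_bundle
        fp1 = dataset_fingerprint(records)
        fp2 = dataset_fingerprint(list(reversed(records)))
        assert fp1 == fp2


class TestReplayDeterminism:
    def test_pipeline_reproduces_cv_summary(self):
        """Re-running the pipeline from the same config and seed (the
        information a run manifest records) reproduces the CV summary."""
        records, _ = generate_dataset(
            SyntheticSpec(n_compounds=60, noise_sd=0.1, seed=13)
        )
        kwargs = dict(max_atoms=3, n_selected=8, NO=3, NI=2, seed=4,
                      max_epochs=100)
        a = fit_pipeline(records, **kwargs).cv_result.summary()
        b = fit_pipeline(records, **kwargs).cv_result.summary()
        assert a == b


class TestSDFReader:
    def test_sdf_round_trip_with_endpoint(self, tmp_path):
        from rdkit import Chem

        from fragbb.molgraph import read_sdf

        path = tmp_path / "mols.sdf"
        writer = Chem.SDWriter(str(path))
        for name, smi, val in [("mol1", "CCO", 0.2), ("mol2", "c1ccccc1", -0.4)]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("_Name", name)
            mol.SetProp("logbb", str(val))
            writer.write(mol)
        writer.close()
        records, rejects = read_sdf(path)
        assert rejects == []
        assert [r.id for r in records] == ["mol1", "mol2"]
        assert records[0].logbb == pytest.approx(0.2)
        assert records[1].graph.n_atoms == 6


class TestCLI:
    def test_synth_featurize_train_predict_cycle(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data.csv"
        result = runner.invoke(cli, [
            "synth", "--out", str(data), "--n", "80", "--seed", "3",
        ])
        assert result.exit_code == 0, result.output

        matrix = tmp_path / "matrix.tsv"
        result = runner.invoke(cli, [
            "featurize", str(data), "--out", str(matrix), "--max-atoms", "3",
        ])
        assert result.exit_code == 0, result.output
        assert matrix.exists()

        model = tmp_path / "model.joblib"
        summary = tmp_path / "summary.json"
        result = runner.invoke(cli, [
            "train", str(data), "--out", str(model),
            "--summary", str(summary), "--max-atoms", "3",
            "--n-selected", "10", "--no", "3", "--ni", "2", "--seed", "1",
        ])
        assert result.exit_code == 0, result.output
        stats = json.loads(summary.read_text())
        assert "Q2" in stats["cv"]

        preds = tmp_path / "preds.csv"
        result = runner.invoke(cli, [
            "predict", str(model), str(data), "--out", str(preds),
        ])
        assert result.exit_code == 0, result.output
        df = pd.read_csv(preds)
        assert {"id", "status", "mean", "sd"} <= set(df.columns)

        contrib = tmp_path / "contrib.csv"
        result = runner.invoke(cli, [
            "interpret", str(model), str(data), "--out", str(contrib),
        ])
        assert result.exit_code == 0, result.output
        cdf = pd.read_csv(contrib)
        assert "mean_contribution" in cdf.columns

        report = tmp_path / "validation.json"
        result = runner.invoke(cli, [
            "validate", str(model), str(data), "--train-csv", str(data),
            "--out", str(report),
        ])
        assert result.exit_code == 0, result.output
        payload = json.loads(report.read_text())
        assert "full" in payload and "overlapping" in payload

    def test_hypersearch_command(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data.csv"
        records, coefs = generate_dataset(
            SyntheticSpec(n_compounds=60, noise_sd=0.1, seed=8)
        )
        write_dataset_csv(records, data)
        config = tmp_path / "space.yaml"
        config.write_text(
            "space:\n"
            "  max_fragment_atoms: [3]\n"
            "  n_selected: [4, 10]\n"
            "  hidden_ratio: [0.3, 0.5]\n"
            "  dropout_p: [0.0, 0.0]\n"
            "fixed:\n"
            "  max_epochs: 50\n"
        )
        log = tmp_path / "trials.jsonl"
        result = runner.invoke(cli, [
            "hypersearch", str(data), "--budget", "2", "--seed", "1",
            "--config", str(config), "--log", str(log),
        ])
        assert result.exit_code == 0, result.output
        assert len(log.read_text().splitlines()) == 2
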