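"""Generator contracts: determinism, validator compliance, planted-truth
recovery in the noiseless limit, and the truth-evaluation report."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from ptmdyn.io_tables import read_fasta, read_interactions, read_site_table
from ptmdyn.site_processing import aggregate_replicates, filter_sites
from ptmdyn.synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_class_benchmark,
    generate_dataset,
    truth_evaluation,
)
from ptmdyn.temporal import UNREGULATED, classify_rule_based
from ptmdyn.ub import chain_linkage_abundance


def _dir_digest(path: Path) -> str:
    digest = hashlib.sha256()
    for f in sorted(path.iterdir()):
        digest.update(f.name.encode())
        digest.update(f.read_bytes())
    return digest.hexdigest()


class TestDeterminism:
    def test_same_seed_regenerates_byte_identical_bundle(self, tmp_path):
        for name in ("a", "b"):
            generate_dataset(SyntheticConfig(n_proteins=30, seed=11)).write(
                tmp_path / name
            )
        assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        generate_dataset(SyntheticConfig(n_proteins=30, seed=1)).write(tmp_path / "a")
        generate_dataset(SyntheticConfig(n_proteins=30, seed=2)).write(tmp_path / "b")
        assert _dir_digest(tmp_path / "a") != _dir_digest(tmp_path / "b")


class TestConfigValidation:
    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1).validate()

    def test_motif_offset_beyond_window_rejected(self):
        from ptmdyn.synthetic import MotifSpec

        with pytest.raises(ValueError, match="window"):
            SyntheticConfig(motif_spec=MotifSpec(offset=20)).validate()

    def test_linkage_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="linkage"):
            SyntheticConfig(linkage_fractions={"K48": 0.5}).validate()


class TestGeneratedTablesAreValid:
    def test_written_bundle_passes_all_readers(self, tmp_path):
        dataset = generate_dataset(SyntheticConfig(n_proteins=25, seed=3))
        paths = dataset.write(tmp_path)
        sequences = read_fasta(paths["fasta"]).sequences
        for ptm in ("acetyl", "phospho", "ubiquityl", "wcp"):
            records = read_site_table(paths[ptm], ptm)
            assert records == dataset.site_records[ptm]
            for r in records:
                r.validate()
                if ptm != "wcp":
                    # planted residue letter matches the sequence
                    assert sequences[r.accession][r.position - 1] == r.residue
        edges = read_interactions(paths["interactions"], 0.8)
        assert edges and all(e.score > 0.8 for e in edges)

    def test_manifest_records_seed(self, tmp_path):
        paths = generate_dataset(SyntheticConfig(n_proteins=10, seed=42)).write(tmp_path)
        assert "seed=42" in paths["manifest"].read_text()


class TestNoiselessRecovery:
    def test_rule_labels_recover_planted_classes_exactly(self):
        cfg = SyntheticConfig(
            n_proteins=60, noise_sd=0.0, missing_prob=0.0, low_locprob_frac=0.0, seed=5
        )
        dataset = generate_dataset(cfg)
        records = [
            r
            for ptm in ("acetyl", "phospho", "ubiquityl")
            for r in dataset.site_records[ptm]
            if r.condition == "untreated"
        ]
        profiles = aggregate_replicates(filter_sites(records))
        truth = dataset.truth.site_class
        assert profiles
        for p in profiles:
            assert classify_rule_based(p).six_class_label == truth[p.key]

    def test_linkage_round_trip_exact(self):
        cfg = SyntheticConfig(n_proteins=5, seed=7)
        dataset = generate_dataset(cfg)
        result = chain_linkage_abundance(
            [r for r in dataset.site_records["ubiquityl"] if r.condition == "untreated"],
            ["SYNUBB"],
        )
        for name, planted in cfg.linkage_fractions.items():
            assert result.fractions[name] == pytest.approx(planted, abs=1e-12)
        assert sum(result.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_unregulated_sites_stay_below_threshold_at_moderate_noise():
    # Gaussian tail: with noise sd 0.2 and n = 3 replicates the mean has
    # sd ~ 0.115, so P(|mean| >= 1) is negligible; >= 99% must stay below 1
    cfg = SyntheticConfig(n_proteins=150, noise_sd=0.2, seed=13)
    dataset = generate_dataset(cfg)
    records = [
        r
        for ptm in ("acetyl", "phospho", "ubiquityl")
        for r in dataset.site_records[ptm]
        if r.condition == "untreated"
        and dataset.truth.site_class[r.key] == UNREGULATED
    ]
    profiles = aggregate_replicates(records, min_replicates=1)
    means = [
        m
        for p in profiles
        for m in (p.mean_log2_05h, p.mean_log2_2h)
        if m is not None
    ]
    assert len(means) > 200
    assert np.mean(np.abs(means) < 1.0) >= 0.99


class TestClassBenchmark:
    def test_balanced_counts_and_determinism(self):
        profiles, labels = generate_class_benchmark(10, seed=1)
        assert len(profiles) == 60
        assert all(labels.count(c) == 10 for c in set(labels))
        again = generate_class_benchmark(10, seed=1)
        assert [p.mean_log2_05h for p in profiles] == [
            p.mean_log2_05h for p in again[0]
        ]

    def test_noiseless_benchmark_classifies_perfectly(self):
        profiles, labels = generate_class_benchmark(5, noise_sd=0.0, seed=2)
        for p, label in zip(profiles, labels):
            assert classify_rule_based(p).six_class_label == label


class TestTruthEvaluation:
    def _truth(self):
        return GroundTruth(
            site_class={("P", i, "phospho", "untreated"): "slow-up" for i in range(4)},
            protein_group={"P": "syn"},
            ub_verdict={("P", 1, "ubiquityl", "mg132"): "degradative"},
        )

    def test_perfect_predictions_score_one(self):
        truth = self._truth()
        preds = {
            "site_class": dict(truth.site_class),
            "protein_group": dict(truth.protein_group),
            "ub_verdict": dict(truth.ub_verdict),
        }
        report = truth_evaluation(preds, truth)
        assert all(info["accuracy"] == 1.0 for info in report.values())

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(17)
        labels = ["slow-up", "slow-down", "fast-lasting-up"]
        truth = GroundTruth(
            site_class={
                ("P", i, "phospho", "untreated"): labels[i % 3] for i in range(3000)
            }
        )
        preds = {
            "site_class": {
                k: labels[int(rng.integers(3))] for k in truth.site_class
            }
        }
        report = truth_evaluation(preds, truth)
        # analytic chance level for uniform guessing over 3 classes
        assert report["site_class"]["accuracy"] == pytest.approx(1 / 3, abs=0.03)

    def test_empty_predictions_flagged_not_crashing(self):
        report = truth_evaluation({}, self._truth())
        assert all(info["missing"] for info in report.values())
        report2 = truth_evaluation({"site_class": {}}, self._truth())
        assert report2["site_class"]["n"] == 0
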