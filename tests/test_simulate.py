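"""Synthetic study generator: tree shape, planted signal, determinism."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from meshmine.mesh import parse_mesh, pwk
from meshmine.pipeline import PipelineOptions
from meshmine.simulate import SimConfig, generate_study, generate_tree, run_end_to_end, write_study


class TestGenerateTree:
    def test_counts_by_construction(self):
        cfg = SimConfig(tree_depth=2, tree_branching=3, categories=("A",))
        d = generate_tree(cfg)
        assert len(d) == 3
        assert all(depth == 2 for depth in d.keyword_depth.values())

    def test_complete_bary_counts_across_levels(self):
        cfg = SimConfig(tree_depth=4, tree_branching=2, categories=("A", "C"))
        d = generate_tree(cfg)
        # per category: 2 + 4 + 8 nodes at levels 2..4
        assert len(d) == 2 * (2 + 4 + 8)

    def test_deep_tree_straddles_the_pwk_threshold(self):
        d = generate_tree(SimConfig(tree_depth=6))
        penalties = {pwk(depth) for depth in d.keyword_depth.values()}
        assert 1.0 in penalties and any(p < 1 for p in penalties)

    def test_fixture_file_is_deterministic(self, tmp_path):
        cfg = SimConfig(seed=3)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        generate_tree(cfg).to_tabular(p1)
        generate_tree(cfg).to_tabular(p2)
        assert p1.read_bytes() == p2.read_bytes()
        # and round-trips through the parser
        assert len(parse_mesh(p1, format="tabular")) == len(generate_tree(cfg))


class TestGenerateStudy:
    def test_document_count(self):
        cfg = SimConfig(n_genes=2, n_diseases=2, n_known_pairs=2, docs_per_entity=3, seed=0)
        study = generate_study(cfg)
        assert len(study.records) == (2 + 2) * 3

    def test_full_overlap_without_noise_separates_known_pairs(self):
        cfg = SimConfig(
            n_genes=4, n_diseases=4, n_known_pairs=3, theta=1.0, noise_rate=0.0,
            signature_size=6, seed=11,
        )
        study = generate_study(cfg)
        result, _ = run_end_to_end(cfg, study=study)
        table = result.table
        known = table[table["is_known"]]["cosine"]
        unknown = table[~table["is_known"]]["cosine"]
        assert known.min() > unknown.max()

    def test_zero_overlap_without_noise_gives_orthogonal_known_pairs(self):
        cfg = SimConfig(
            n_genes=3, n_diseases=3, n_known_pairs=3, theta=0.0, noise_rate=0.0, seed=5,
        )
        result, _ = run_end_to_end(cfg)
        known = result.table[result.table["is_known"]]["cosine"]
        assert (known == 0).all()

    def test_signature_demand_error_suggests_larger_tree(self):
        cfg = SimConfig(n_genes=200, n_diseases=50, n_known_pairs=100, signature_size=50,
                        tree_depth=5, tree_branching=2)
        with pytest.raises(ValueError, match="tree"):
            generate_study(cfg)

    @pytest.mark.parametrize("field, value", [
        ("n_genes", 0), ("theta", 1.5), ("noise_rate", 1.0), ("tree_depth", 1),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_known_pairs_fit_in_cross_product(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=2, n_diseases=2, n_known_pairs=5)


class TestDeterminism:
    def test_same_seed_identical_study_files(self, tmp_path):
        cfg = SimConfig(n_genes=5, n_diseases=3, n_known_pairs=4, seed=7)
        d1 = write_study(generate_study(cfg), tmp_path / "run1")
        d2 = write_study(generate_study(cfg), tmp_path / "run2")
        for name in ("corpus.jsonl", "dict.tsv", "genes.tsv", "diseases.tsv", "gold.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_end_to_end_bit_identical_tables(self):
        cfg = SimConfig(n_genes=8, n_diseases=5, n_known_pairs=6, seed=19)
        r1, _ = run_end_to_end(cfg)
        r2, _ = run_end_to_end(cfg)
        assert r1.table.equals(r2.table)
        assert r1.curve.equals(r2.curve)


class TestPlantedSignalStatistics:
    def test_known_pairs_outrank_unknown_at_default_conditions(self):
        cfg = SimConfig(n_genes=10, n_diseases=6, n_known_pairs=8, theta=0.8,
                        noise_rate=0.1, seed=42)
        result, summary = run_end_to_end(cfg)
        table = result.table
        known = table[table["is_known"]]["cosine"]
        unknown = table[~table["is_known"]]["cosine"]
        assert known.median() > unknown.median()
        assert summary["top_k_precision"] >= 0.8

    def test_null_study_known_scores_indistinguishable(self):
        pvals = []
        for seed in range(1, 4):
            cfg = SimConfig(n_genes=10, n_diseases=6, n_known_pairs=8, theta=0.0,
                            noise_rate=0.1, seed=seed)
            result, _ = run_end_to_end(cfg)
            table = result.table
            known = table[table["is_known"]]["cosine"]
            unknown = table[~table["is_known"]]["cosine"]
            pvals.append(sps.mannwhitneyu(known, unknown).pvalue)
        assert all(p > 0.01 for p in pvals)

    def test_location_weighting_helps_when_signal_sits_in_title_and_mesh(self):
        cfg = SimConfig(n_genes=10, n_diseases=6, n_known_pairs=8, signal_in_sentences=False,
                        noise_rate=0.3, seed=23)
        study = generate_study(cfg)
        weighted, _ = run_end_to_end(cfg, study=study)
        uniform, _ = run_end_to_end(cfg, options=PipelineOptions().without_weight_matrix(), study=study)
        thr_w = np.quantile(weighted.table["cosine"], 0.9)
        thr_u = np.quantile(uniform.table["cosine"], 0.9)
        from meshmine.evaluation import precision_at
        p_w = precision_at(weighted.table, study.gold, float(thr_w))
        p_u = precision_at(uniform.table, study.gold, float(thr_u))
        assert p_w >= p_u


def test_study_manifest_records_config(tmp_path):
    cfg = SimConfig(n_genes=3, n_diseases=2, n_known_pairs=2, seed=4)
    outdir = write_study(generate_study(cfg), tmp_path / "study")
    manifest = json.loads((outdir / "manifest.json").read_text())
    assert manifest["config"]["seed"] == 4
    assert manifest["n_records"] == (3 + 2) * cfg.docs_per_entity
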