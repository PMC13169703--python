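"""Mann-Whitney U test and end-to-end pipeline orchestration."""

import filecmp
import json

import numpy as np
import pytest
from scipy import stats as sps

from helpers import mw_exact_oracle, pipeline_config, small_panel_config
from trnapanel.stats_report import (
    PipelineConfig,
    analyze,
    inputs_from_panel,
    load_inputs,
    mann_whitney_u,
    run_pipeline,
)
from trnapanel.synthetic_data import simulate_panel


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.pvalue == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_multisets_give_half_product(self):
        x = [1.0, 2.0, 5.0]
        res = mann_whitney_u(x, x)
        assert res.U == pytest.approx(len(x) * len(x) / 2)

    def test_singletons(self):
        res = mann_whitney_u([1.0], [2.0])
        assert res.U == 0 and res.pvalue == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_enumeration_oracle_on_random_small_samples(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 10 - n1 + 1))
            # small integer support so ties occur frequently
            x = rng.integers(0, 5, n1).astype(float).tolist()
            y = rng.integers(0, 5, n2).astype(float).tolist()
            got = mann_whitney_u(x, y)
            u_oracle, p_oracle = mw_exact_oracle(x, y)
            assert got.U == pytest.approx(u_oracle)
            assert got.pvalue == pytest.approx(p_oracle)

    def test_large_sample_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0, 1, 30).tolist()
        y = rng.normal(0.8, 1, 25).tolist()
        got = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert got.method == "normal"
        assert got.U == pytest.approx(ref.statistic)
        assert got.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestPipeline:
    SUMMARY_KEYS = {
        "n_loci", "n_high", "n_low", "n_mature", "n_rejections", "n_sets",
        "n_missing", "n_pseudo", "n_conflict", "n_unique_sequences",
        "max_copy_range", "n_single_copy_conserved", "pol3_classes",
        "replicate_concordance_r", "max_variant_count", "n_identity_changes",
        "n_conversion_events", "n_recurrent_pairs", "strain_count_histogram",
        "mannwhitney", "profiles", "cross_species_status",
    }

    def test_summary_schema_on_default_panel(self, default_analysis):
        assert self.SUMMARY_KEYS <= set(default_analysis.summary)
        s = default_analysis.summary
        assert s["n_loci"] == s["n_mature"] + s["n_rejections"]
        assert s["n_high"] + s["n_low"] == s["n_loci"]

    def test_every_locus_analyzed_or_discarded_with_reason(self, default_analysis):
        n_loci = sum(
            len(v) for v in default_analysis.inputs.loci_by_genome.values()
        )
        n_mature = sum(len(v) for v in default_analysis.mature_by_genome.values())
        assert n_mature + len(default_analysis.rejections) == n_loci

    def test_panel_without_trna_like_has_no_transcribed_like_class(self):
        cfg = pipeline_config()
        panel = simulate_panel(small_panel_config(31, fraction_trna_like=0.0))
        res = analyze(inputs_from_panel(panel, cfg), cfg)
        assert res.summary["pol3_classes"].get("transcribed_tRNA_like", 0) == 0
        assert res.summary["n_low"] == 0

    def test_file_roundtrip_matches_in_memory_analysis(self, tmp_path):
        cfg = pipeline_config()
        panel = simulate_panel(small_panel_config(33))
        panel.write(tmp_path / "panel")
        res_files = run_pipeline(cfg, tmp_path / "panel", tmp_path / "out")
        res_mem = analyze(inputs_from_panel(panel, cfg), cfg)
        for key in ("n_loci", "n_sets", "n_missing", "n_pseudo",
                    "n_conversion_events", "n_unique_sequences"):
            assert res_files.summary[key] == res_mem.summary[key]
        out = tmp_path / "out"
        for name in (
            "ortholog_sets.tsv", "copy_table.tsv", "pol3_scores.tsv",
            "conversion_events.tsv", "conversion_recurrence.tsv",
            "rejections.tsv", "edge_rejections.tsv", "summary.json",
            "pipeline.log",
        ):
            assert (out / name).exists()

    def test_rerun_same_seed_is_byte_identical(self, tmp_path):
        cfg = pipeline_config()
        panel_dir = tmp_path / "panel"
        simulate_panel(small_panel_config(34)).write(panel_dir)
        run_pipeline(cfg, panel_dir, tmp_path / "o1")
        run_pipeline(cfg, panel_dir, tmp_path / "o2")
        names = sorted(p.name for p in (tmp_path / "o1").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "o1", tmp_path / "o2", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_genomic_copy_identity_switch(self):
        # identity by gene body: His G-1/CCA no longer merge or split rows,
        # and intron-carrying loci group by their genomic (intron-included)
        # sequence instead of the mature one
        cfg_m = pipeline_config()
        cfg_g = pipeline_config(copy_identity="genomic")
        panel = simulate_panel(small_panel_config(35, intron_fraction=0.3))
        inputs = inputs_from_panel(panel, cfg_m)
        res_m = analyze(inputs, cfg_m)
        res_g = analyze(inputs, cfg_g)
        for g in inputs.genomes:
            assert int(res_g.copy_table.df[g].sum()) == len(
                inputs.loci_by_genome[g]
            )
        # mature projection is a bijection on N-free loci here, so the two
        # identity notions must agree on total copies per genome
        assert res_m.copy_table.df.values.sum() <= res_g.copy_table.df.values.sum()

    def test_config_round_trip(self):
        cfg = PipelineConfig(seed=5, outgroup=("rat",))
        assert PipelineConfig.from_dict(cfg.to_dict()) == cfg


class TestCli:
    def test_simulate_and_run_all(self, tmp_path):
        from click.testing import CliRunner

        from trnapanel.cli import main

        runner = CliRunner()
        panel_cfg = tmp_path / "panel.yaml"
        panel_cfg.write_text("n_strains: 5\nn_families: 8\n")
        panel_dir = str(tmp_path / "panel")
        r = runner.invoke(
            main,
            ["simulate", "--seed", "3", "--outdir", panel_dir, "--config", str(panel_cfg)],
        )
        assert r.exit_code == 0, r.output
        out_dir = str(tmp_path / "out")
        r = runner.invoke(
            main, ["run-all", "--input", panel_dir, "--outdir", out_dir]
        )
        assert r.exit_code == 0, r.output
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["n_sets"] > 0
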