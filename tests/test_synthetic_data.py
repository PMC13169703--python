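"""Generator contracts: determinism, limit behaviors, ChIP count structure."""

import dataclasses
import filecmp
from pathlib import Path

import numpy as np
import pytest

from helpers import small_panel_config
from trnapanel.pol3 import pol3_score
from trnapanel.synthetic_data import (
    PanelConfig,
    build_tree,
    simulate_chip_counts,
    simulate_panel,
)


class TestDeterminism:
    def test_same_seed_gives_identical_in_memory_outputs(self):
        cfg = small_panel_config(9)
        p1, p2 = simulate_panel(cfg), simulate_panel(cfg)
        assert p1.fastas == p2.fastas
        assert p1.trnascan_tables == p2.trnascan_tables
        assert p1.liftover_records == p2.liftover_records
        assert p1.chip_counts == p2.chip_counts

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = small_panel_config(9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_panel(cfg).write(d1)
        simulate_panel(cfg).write(d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seeds_differ(self):
        a = simulate_panel(small_panel_config(1))
        b = simulate_panel(small_panel_config(2))
        assert a.fastas != b.fastas


class TestLimitBehaviors:
    def test_no_mutation_no_conversion_gives_single_variant_sets(self):
        panel = simulate_panel(
            small_panel_config(
                3,
                substitution_rate=0.0,
                conversion_rate=0.0,
                deletion_rate=0.0,
                pseudogenization_rate=0.0,
            )
        )
        truth = panel.truth
        for cid in truth.copy_family:
            matures = {
                lt.mature
                for lt in (truth.per_genome[g][cid] for g in panel.genomes)
                if lt.status == "present"
            }
            assert len(matures) == 1

    def test_forced_strain_deletion_makes_strain_missing_everywhere(self):
        panel = simulate_panel(
            small_panel_config(4, force_delete_strain="strain01")
        )
        assert all(
            lt.status == "absent"
            for lt in panel.truth.per_genome["strain01"].values()
        )

    def test_infeasible_config_errors(self):
        with pytest.raises(ValueError, match="does not fit"):
            simulate_panel(
                small_panel_config(1, n_families=50, max_chrom_len=1000)
            )

    def test_default_topology_counts(self):
        cfg = PanelConfig()
        tree = build_tree(cfg)

        def leaves(node):
            name, _, ch = node
            return [name] if not ch else [x for c in ch for x in leaves(c)]

        tips = leaves(tree)
        assert len(tips) == 18  # 17 strains + outgroup
        assert tips[0] == cfg.outgroup and "divergent" in tips


class TestChipCounts:
    def test_null_configuration_removes_class_separation(self):
        panel = simulate_panel(
            small_panel_config(5, chip_mean_active=20.0, chip_mean_silent=20.0)
        )
        truth = panel.truth
        ann = truth.annotated(panel.reference)
        scores = {"active": [], "silent": []}
        for lid, (t, c) in panel.chip_counts[0].items():
            cls = "active" if any(
                lt.locus_id == lid and lt.active for lt in ann.values()
            ) else "silent"
            scores[cls].append(pol3_score(t, c))
        if scores["active"] and scores["silent"]:
            assert abs(np.mean(scores["active"]) - np.mean(scores["silent"])) < 0.3

    def test_large_counts_concentrate_near_cap(self):
        # 64x mean ratio at high counts: expected log2 ratio approaches the
        # cap; cross-checked against a direct Monte-Carlo draw of the same
        # negative-binomial model
        cfg = small_panel_config(
            6,
            chip_mean_active=64_000.0,
            chip_mean_silent=1_000.0,
            chip_dispersion=50.0,
            active_fraction=1.0,
            trna_like_active_fraction=1.0,
        )
        panel = simulate_panel(cfg)
        scores = [pol3_score(t, c) for t, c in panel.chip_counts[0].values()]
        rng = np.random.default_rng(123)
        n = 10_000

        def nb(mean, disp):
            return rng.negative_binomial(disp, disp / (disp + mean), n)

        oracle = np.clip(
            np.log2((nb(64_000.0, 50.0) + 20) / (nb(1_000.0, 50.0) + 20)), 0, 6
        )
        assert np.mean(oracle) > 5.5
        assert abs(np.mean(scores) - np.mean(oracle)) < 0.2

    def test_zero_mean_control_is_finite(self):
        panel = simulate_panel(small_panel_config(7, chip_mean_silent=0.0))
        for t, c in panel.chip_counts[0].items():
            pass
        scores = [pol3_score(t, c) for t, c in panel.chip_counts[0].values()]
        assert all(np.isfinite(scores))

    def test_rounds_are_independent_replicates(self):
        panel = simulate_panel(small_panel_config(8, n_chip_replicates=2))
        assert panel.chip_counts[0] != panel.chip_counts[1]
        assert set(panel.chip_counts[0]) == set(panel.chip_counts[1])


class TestTruthConsistency:
    def test_every_truth_locus_resolves_to_an_emitted_annotation(self, default_panel):
        from trnapanel.annotations_io import parse_trnascan_table

        truth = default_panel.truth
        for g in default_panel.genomes:
            loci = {
                l.locus_id: l
                for l in parse_trnascan_table(default_panel.trnascan_tables[g], g)
            }
            for lt in truth.per_genome[g].values():
                if lt.status == "present":
                    loc = loci[lt.locus_id]
                    assert (loc.start, loc.end, loc.strand) == (
                        lt.start,
                        lt.end,
                        lt.strand,
                    )
                    assert loc.isotype == lt.isotype
            # and nothing annotated beyond the truth
            truth_ids = {
                lt.locus_id
                for lt in truth.per_genome[g].values()
                if lt.status == "present"
            }
            assert set(loci) == truth_ids

    def test_mature_truth_matches_projection_rules(self, default_panel, default_config):
        # the generator's mature sequences and the pipeline's projection
        # must agree locus by locus
        from trnapanel.annotations_io import parse_trnascan_table
        from trnapanel.mature_sequence import extract_gene_body, project_mature

        g = default_panel.reference
        truth = default_panel.truth
        loci = parse_trnascan_table(
            default_panel.trnascan_tables[g], g, default_config.score_floor
        )
        by_id = {
            lt.locus_id: lt
            for lt in truth.per_genome[g].values()
            if lt.status == "present"
        }
        for loc in loci:
            body = extract_gene_body(default_panel.fastas[g], loc)
            res = project_mature(loc, body)
            assert res.seq == by_id[loc.locus_id].mature
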