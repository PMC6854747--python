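"""DTL simulator: determinism, conservation, null congruence, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from hybridtrace import tree_io
from hybridtrace.clade_analysis import is_monophyletic
from hybridtrace.phylo_distance import cophenetic_matrix, nearest_neighbor_origin
from hybridtrace.synthetic_data import (
    SimConfig,
    SimResult,
    evaluate_recovery,
    gene_species_rf,
    simulate,
    simulate_species_tree,
    write_sim,
)


def null_config(seed, **kw):
    base = dict(dup_rate=0.0, loss_rate=0.0, transfer_rate=0.0,
                branch_length_noise_cv=0.0, seed=seed)
    base.update(kw)
    return SimConfig(**base)


class TestSpeciesTree:
    def test_shape_and_sections(self):
        tree, sections = simulate_species_tree(SimConfig(n_sections=2,
                                                         species_per_section=2))
        tips = tree_io.tip_labels(tree)
        assert len(tips) == 4
        assert set(sections.values()) == {"sec1", "sec2"}
        for sec in ("sec1", "sec2"):
            members = {t for t in tips if sections[t] == sec}
            assert is_monophyletic(tree, members).is_monophyletic

    def test_sections_monophyletic_at_defaults(self):
        tree, sections = simulate_species_tree(SimConfig(seed=5))
        for sec in set(sections.values()):
            members = {t for t, s in sections.items() if s == sec}
            assert is_monophyletic(tree, members).is_monophyletic

    def test_same_seed_same_newick(self):
        a, _ = simulate_species_tree(SimConfig(seed=11))
        b, _ = simulate_species_tree(SimConfig(seed=11))
        assert tree_io.write_newick(a) == tree_io.write_newick(b)

    def test_height_and_shallow_sections(self):
        cfg = SimConfig(seed=2)
        tree, sections = simulate_species_tree(cfg)
        dm = cophenetic_matrix(tree)
        within, between = [], []
        for i, a in enumerate(dm.tips):
            for b in dm.tips[i + 1:]:
                (within if sections[a] == sections[b] else between).append(
                    dm.distance(a, b)
                )
        assert max(within) <= 2 * cfg.within_section_divergence + 1e-9
        assert min(between) > 2 * 0.75 * cfg.species_tree_height - 1e-9


class TestGeneFamily:
    def test_deterministic_outputs(self, tmp_path):
        cfg = SimConfig(seed=42)
        a, b = simulate(cfg), simulate(cfg)
        assert tree_io.write_newick(a.gene_tree) == tree_io.write_newick(b.gene_tree)
        assert a.events == b.events
        pa, pb = tmp_path / "a", tmp_path / "b"
        write_sim(a, pa)
        write_sim(b, pb)
        for name in ("species_tree.nwk", "gene_tree.nwk", "tip_metadata.tsv",
                     "events.tsv"):
            assert (pa / name).read_bytes() == (pb / name).read_bytes()

    def test_null_process_congruent_to_species_tree(self):
        for seed in range(10):
            sim = simulate(null_config(seed))
            assert gene_species_rf(sim) == 0
            assert sim.events == []
            assert not any(sim.truth.values())

    def test_no_transfer_rate_means_no_transfer_events(self):
        for seed in range(5):
            sim = simulate(SimConfig(seed=seed, transfer_rate=0.0))
            assert all(e.kind != "transfer" for e in sim.events)
            assert not any(sim.truth.values())

    def test_copy_conservation(self):
        """Extant tips = root copies + duplications + transfers + lineage
        splits at speciations - losses, per the event log."""
        for seed in range(20):
            sim = simulate(SimConfig(seed=seed))
            births = sum(1 for e in sim.events if e.kind in ("duplication", "transfer"))
            deaths = sum(1 for e in sim.events if e.kind == "loss")
            expected = (
                sim.config.root_gene_copies + births + deaths * 0
                + sim.n_speciation_splits - deaths
            )
            assert len(sim.truth) == expected

    def test_pure_birth_expectation(self):
        """Mean extant copies under duplication only matches the Yule
        expectation S * exp(dup_rate * height) within 3 standard errors."""
        # two single-species sections: both root-to-tip paths span exactly
        # the tree height, so E[tips] = 2 * exp(dup_rate * height)
        lam, height, reps = 0.5, 1.0, 200
        counts = []
        for seed in range(reps):
            sim = simulate(
                SimConfig(
                    n_sections=2, species_per_section=1,
                    species_tree_height=height,
                    dup_rate=lam, loss_rate=0.0, transfer_rate=0.0,
                    branch_length_noise_cv=0.0, seed=seed,
                )
            )
            counts.append(len(sim.truth))
        counts = np.array(counts, dtype=float)
        expected = 2 * math.exp(lam * height)
        se = counts.std(ddof=1) / math.sqrt(reps)
        assert abs(counts.mean() - expected) <= 3 * se

    def test_transfer_events_logged_with_distinct_endpoints(self):
        sim = simulate(SimConfig(seed=8, transfer_rate=1.0))
        transfers = [e for e in sim.events if e.kind == "transfer"]
        assert transfers
        for e in transfers:
            assert e.recipient_lineage is not None
            assert e.recipient_lineage != e.donor_lineage

    def test_all_rates_high_can_go_extinct_flagged(self):
        extinct_seen = False
        for seed in range(30):
            sim = simulate(SimConfig(seed=seed, dup_rate=0.0, loss_rate=5.0,
                                     transfer_rate=0.0))
            if sim.extinct:
                extinct_seen = True
                assert sim.gene_tree is None and sim.truth == {}
        assert extinct_seen

    def test_meta_covers_every_gene_tip(self):
        sim = simulate(SimConfig(seed=3))
        assert sorted(tree_io.tip_labels(sim.gene_tree)) == sorted(sim.meta.index)
        assert set(sim.meta["section"]) <= {"sec1", "sec2", "sec3", "sec4"}


class TestEvaluateRecovery:
    def test_hand_grafted_transfer_recovered_exactly(self):
        """One tip of section B grafted inside the section-A clade: the
        cross-section nearest-neighbor call finds it and nothing else."""
        gene_tree = tree_io.parse_newick(
            "(((a1_g:0.05,a2_g:0.05):0.1,x_g:0.2):1.0,"
            "((b1_g:0.05,b2_g:0.05):0.05,b3_g:0.1):1.0);"
        )
        meta = tree_io.build_metadata(
            ["a1_g", "a2_g", "x_g", "b1_g", "b2_g", "b3_g"],
            ["a1", "a2", "x", "b1", "b2", "b3"],
            ["A", "A", "B", "B", "B", "B"],
            sm_class="hybrid",
        )
        sim = SimResult(
            config=SimConfig(), species_tree=None, gene_tree=gene_tree,
            events=[], meta=meta,
            truth={"a1_g": False, "a2_g": False, "x_g": True,
                   "b1_g": False, "b2_g": False, "b3_g": False},
            extinct=False,
        )
        dm = cophenetic_matrix(gene_tree)
        nn = nearest_neighbor_origin(dm, meta)
        rec = evaluate_recovery(sim, nn, dm)
        assert rec.recall == 1.0 and rec.precision == 1.0
        assert rec.n_called == rec.n_truth == 1

    def test_no_positives_reports_undefined_recall(self):
        sim = simulate(null_config(1))
        dm = cophenetic_matrix(sim.gene_tree)
        nn = nearest_neighbor_origin(dm, sim.meta)
        rec = evaluate_recovery(sim, nn, dm)
        assert rec.recall is None
        assert rec.n_called == 0  # section-pure tree: all neighbors same-section

    def test_recall_increases_with_cross_section_probability(self):
        """Monte-Carlo trend: the detector sees more of the truth when
        transfers preferentially cross sections."""
        def mean_recall(p, reps=60):
            vals = []
            for seed in range(reps):
                sim = simulate(SimConfig(seed=seed, transfer_rate=0.3,
                                         transfer_cross_section_prob=p))
                if sim.extinct or len(sim.truth) < 2:
                    continue
                dm = cophenetic_matrix(sim.gene_tree)
                rec = evaluate_recovery(
                    sim, nearest_neighbor_origin(dm, sim.meta)
                )
                if rec.recall is not None:
                    vals.append(rec.recall)
            return np.mean(vals)

        assert mean_recall(1.0) > mean_recall(0.1)
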