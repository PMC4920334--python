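"""Determinism and ground-truth properties of the generators."""

import numpy as np
import pytest
from scipy import stats

from paleoroute.orthology_screen import candidate_mean_distance, distance_summary
from paleoroute.phylo_io import DEFAULT_HABITAT_STATES
from paleoroute.timescale import validate_chronogram
from paleoroute import synthetic_data as synth


class TestSpeciesTree:
    def test_exact_tip_count(self):
        for n in (3, 7, 30):
            assert synth.simulate_species_tree(n, 1).n_tips() == n

    def test_same_seed_identical_newick(self):
        a = synth.simulate_species_tree(10, 5).to_newick()
        b = synth.simulate_species_tree(10, 5).to_newick()
        assert a == b

    def test_different_seed_differs(self):
        assert synth.simulate_species_tree(10, 5).to_newick() != \
            synth.simulate_species_tree(10, 6).to_newick()

    def test_strictly_positive_branch_lengths(self):
        tree = synth.simulate_species_tree(25, 2)
        for edge in tree.dtree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length > 0


class TestGeneFamily:
    def test_zero_duplication_rate_reproduces_species_tree(self):
        species = synth.simulate_species_tree(8, 3)
        cfg = synth.SimConfig(seed=3, duplication_rate=0.0)
        gene, truth = synth.simulate_gene_family(species, cfg)
        assert gene.to_newick() == species.to_newick()
        assert set(truth.labels.values()) == {synth.ORTHOLOGUE}

    def test_same_seed_identical_truth(self):
        species = synth.simulate_species_tree(8, 3)
        cfg = synth.SimConfig(seed=12, duplication_rate=2.0)
        _, t1 = synth.simulate_gene_family(species, cfg)
        _, t2 = synth.simulate_gene_family(species, cfg)
        assert t1.labels == t2.labels

    def test_planted_out_paralog_is_distant(self):
        species = synth.simulate_species_tree(10, 7)
        synth._scale_tree(species, 0.5 / synth._tree_depth(species))
        cfg = synth.SimConfig(seed=7)
        gene, truth = synth.plant_out_paralog(species, cfg)
        cand = sorted(species.tip_names)[0]
        accepted = set(species.tip_names) - {cand}
        summary = distance_summary(gene, accepted)
        d_orth = candidate_mean_distance(gene, cand, accepted)
        d_para = candidate_mean_distance(gene, cand + "_d1", accepted)
        assert d_para > d_orth
        assert d_para > summary.threshold
        assert truth.labels[cand + "_d1"] == synth.OUT_PARALOG


class TestSequences:
    def test_zero_lengths_identical_sequences(self):
        from paleoroute.phylo_io import Tree

        tree = Tree.from_newick("((A:0,B:0):0,C:0);")
        records, _ = synth.simulate_sequences(tree, 50, 4)
        assert len({r.residues for r in records}) == 1

    def test_divergence_matches_closed_form(self):
        from paleoroute.phylo_io import Tree

        d = 0.1
        tree = Tree.from_newick(f"(A:{d / 2},B:{d / 2});")
        records, _ = synth.simulate_sequences(tree, 10_000, 11)
        a, b = records[0].residues, records[1].residues
        observed = sum(x != y for x, y in zip(a, b))
        p_diff = 1.0 - synth.p_identical(d)
        lo, hi = stats.binom.interval(0.99, 10_000, p_diff)
        assert lo <= observed <= hi

    def test_same_seed_identical(self):
        tree = synth.simulate_species_tree(6, 8)
        r1, _ = synth.simulate_sequences(tree, 40, 9)
        r2, _ = synth.simulate_sequences(tree, 40, 9)
        assert r1 == r2


class TestHits:
    def test_identical_sequences_hit_floor(self):
        assert synth.surrogate_evalue(0.0, 200) == synth.EVALUE_MIN

    def test_random_sequences_not_significant(self):
        # ~95% different is the random-background regime
        assert synth.surrogate_evalue(0.95, 200) >= 1.0

    def test_orthologues_pass_the_prefilter(self):
        # a typical orthologue pair at moderate divergence
        assert synth.surrogate_evalue(0.5, 200) < 1e-20

    def test_monotone_in_difference(self):
        ps = np.linspace(0, 1, 50)
        es = [synth.surrogate_evalue(p, 150) for p in ps]
        assert all(a <= b for a, b in zip(es, es[1:]))

    def test_table_determinism(self):
        tree = synth.simulate_species_tree(5, 13)
        records, _ = synth.simulate_sequences(tree, 60, 13)
        orth = {r.id for r in records[:3]}
        assert synth.simulate_hits(records, orth) == \
            synth.simulate_hits(records, orth)


class TestMkTips:
    def test_zero_rate_keeps_root_state(self):
        from conftest import random_chronogram

        chrono = random_chronogram(10, 21)
        hab = synth.simulate_mk_tips(chrono, 0.0, 5)
        assert len(set(hab.states.values())) == 1

    def test_same_seed_identical(self):
        from conftest import random_chronogram

        chrono = random_chronogram(10, 21)
        assert synth.simulate_mk_tips(chrono, 0.05, 6).states == \
            synth.simulate_mk_tips(chrono, 0.05, 6).states

    def test_stationary_frequencies_near_uniform(self):
        # a long chronogram and fast rate drive tips to the uniform
        # stationary distribution; chi-square over pooled replicates
        from conftest import random_chronogram

        chrono = random_chronogram(10, 22, depth=500.0)
        counts = {s: 0 for s in DEFAULT_HABITAT_STATES}
        for rep in range(150):
            hab = synth.simulate_mk_tips(chrono, 0.05, 1000 + rep)
            for s in hab.states.values():
                counts[s] += 1
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3


class TestBranchiopodCase:
    def test_valid_chronogram_and_three_states(self):
        chrono, habitat = synth.make_branchiopod_like_case(17)
        assert validate_chronogram(chrono).ok
        assert set(habitat.states.values()) == set(DEFAULT_HABITAT_STATES)
        fossils = [t for t, a in habitat.tip_age.items() if a > 0]
        assert len(fossils) == 4

    def test_deterministic(self):
        a, _ = synth.make_branchiopod_like_case(17)
        b, _ = synth.make_branchiopod_like_case(17)
        assert a.to_newick() == b.to_newick()


class TestRateDiagCase:
    def test_planted_fraction_exact(self):
        from paleoroute.rate_diag import branch_rates, median_rate_fraction

        chrono, subs = synth.make_rate_diag_case(23)
        _, frac = median_rate_fraction(branch_rates(chrono, subs))
        assert frac == pytest.approx(0.645)

    def test_null_mode_randomizes_ages_of_at_median_group(self):
        chrono, subs = synth.make_rate_diag_case(23, rootward=False)
        from paleoroute.rate_diag import at_median_mask, branch_rates

        selected, mask = at_median_mask(branch_rates(chrono, subs))
        assert 0 < mask.sum() < len(selected)
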