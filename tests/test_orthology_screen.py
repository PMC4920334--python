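"""The candidate-screening rule engine and its distance machinery."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from paleoroute.errors import InsufficientReferenceError, ValidationError
from paleoroute.orthology_screen import (
    ACCEPTING_RULES,
    ScreenConfig,
    TaxonomyMap,
    build_gene_tree,
    candidate_mean_distance,
    distance_summary,
    filter_hits,
    is_candidate_clade,
    is_misaligned,
    is_plausible,
    nj_tree,
    place_candidate,
    screen_family,
)
from paleoroute.phylo_io import HitRecord, Msa, SequenceRecord, Tree
from paleoroute import synthetic_data as synth

from conftest import rule_scenarios

ACCEPTED5 = {"a1", "a2", "a3", "a4", "a5"}


class TestFilterHits:
    def test_strictly_below_default_threshold(self):
        hits = [HitRecord("q1", "s", 1e-25), HitRecord("q2", "s", 1e-15)]
        assert filter_hits(hits) == {"q1"}

    def test_zero_threshold_empty(self):
        assert filter_hits([HitRecord("q", "s", 0.0)], threshold=0.0) == set()

    def test_query_retained_once(self):
        hits = [HitRecord("q", "s1", 1e-30), HitRecord("q", "s2", 1e-5)]
        assert filter_hits(hits) == {"q"}


def _affine_alignment_oracle(ref: str, cand: str) -> float:
    """Best global alignment score by exhaustive enumeration (short strings).

    Enumerates every monotone pairing of candidate residues with reference
    residues and scores matches with BLOSUM62 plus affine gaps (open -11,
    extend -1), the same scheme the placement aligner uses.
    """
    blosum = substitution_matrices.load("BLOSUM62")

    def gap_cost(length):
        return 0.0 if length == 0 else -11.0 - 1.0 * (length - 1)

    short, long_, flip = (cand, ref, False) if len(cand) <= len(ref) else (ref, cand, True)
    best = -np.inf
    for keep in itertools.combinations(range(len(long_)), len(short)):
        score = 0.0
        prev = -1
        for i, j in enumerate(keep):
            a, b = (long_[j], short[i]) if not flip else (short[i], long_[j])
            score += blosum[a, b]
            score += gap_cost(j - prev - 1)
            prev = j
        score += gap_cost(len(long_) - prev - 1)
        best = max(best, score)
    return best


class TestPlaceCandidate:
    def test_identical_candidate_no_new_columns(self, toy_msa):
        out = place_candidate(toy_msa, SequenceRecord("new", "MKVLIDHG"))
        assert out.n_columns == toy_msa.n_columns
        assert "-" not in out["new"].residues

    def test_two_deletions_give_two_gaps(self, toy_msa):
        out = place_candidate(toy_msa, SequenceRecord("new", "MKLIHG"))
        assert out.n_columns == toy_msa.n_columns
        assert out["new"].residues.count("-") == 2

    def test_score_matches_exhaustive_affine_oracle(self):
        from paleoroute.orthology_screen import _make_aligner

        aligner = _make_aligner()
        pairs = [("MKVLIDHG", "MKLIHG"), ("MKVLI", "MKVLIDH"),
                 ("WCCPG", "WCCG"), ("MKVLIDHG", "MKVLIDHG")]
        for ref, cand in pairs:
            assert aligner.score(ref, cand) == pytest.approx(
                _affine_alignment_oracle(ref, cand))

    def test_existing_rows_only_gain_gap_columns(self, toy_msa):
        out = place_candidate(toy_msa, SequenceRecord("new", "MKVWWWLIDHG"))
        assert out.n_columns == toy_msa.n_columns + 3
        for rec in toy_msa:
            assert out[rec.id].residues.replace("-", "") == rec.ungapped()

    def test_all_gap_candidate_rejected(self, toy_msa):
        with pytest.raises(ValidationError):
            place_candidate(toy_msa, SequenceRecord("new", "----"))


class TestGeneTree:
    def test_identical_sequences_zero_distances(self):
        msa = Msa([SequenceRecord(f"s{i}", "MKVLIDHG") for i in range(3)])
        _, mat = build_gene_tree(msa).patristic_matrix()
        np.testing.assert_allclose(mat, 0.0, atol=1e-9)

    def test_nj_exact_on_additive_distances(self):
        # ((A:2,B:3):1,(C:4,D:5)) gives these additive distances
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 5, 7, 8],
                      [5, 0, 8, 9],
                      [7, 8, 0, 9],
                      [8, 9, 9, 0]], dtype=float)
        tree = nj_tree(labels, D)
        got_labels, got = tree.patristic_matrix()
        assert got_labels == labels
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_two_rows_rejected(self):
        msa = Msa([SequenceRecord("a", "MKV"), SequenceRecord("b", "MKV")])
        with pytest.raises(ValidationError):
            build_gene_tree(msa)

    def test_disjoint_rows_name_the_pair(self):
        msa = Msa([
            SequenceRecord("a", "MKV---"),
            SequenceRecord("b", "---LID"),
            SequenceRecord("c", "MKVLID"),
        ])
        with pytest.raises(ValidationError, match="'a' and 'b'"):
            build_gene_tree(msa)


class TestDistanceStats:
    def test_constant_pairwise_distances(self):
        # star tree: all 4 pairwise distances are 10
        tree = Tree.from_newick("(a1:5,a2:5,a3:5,a4:5);")
        s = distance_summary(tree, {"a1", "a2", "a3", "a4"})
        assert (s.mean, s.sd, s.threshold, s.n_pairs) == (10.0, 0.0, 10.0, 6)

    def test_small_reference_set_rejected(self, basic_tree):
        with pytest.raises(InsufficientReferenceError):
            distance_summary(basic_tree, {"A", "B", "C"})

    def test_five_tips_hand_computed(self):
        tree = Tree.from_newick(
            "((a1:1,a2:1):1,(a3:1,a4:1):1,(a5:1,x:1):1);")
        s = distance_summary(tree, ACCEPTED5)
        # pairs: {2,2,4,4,4,4,4,4,4,4} -> mean 3.6, sample sd sqrt(6.4/9)
        assert s.mean == pytest.approx(3.6)
        assert s.sd == pytest.approx(np.sqrt(6.4 / 9))
        assert s.threshold == pytest.approx(3.6 + 3 * np.sqrt(6.4 / 9))

    def test_candidate_mean_arithmetic(self):
        tree = Tree.from_newick("(a1:2,a2:3,a3:4,a4:5,x:2);")
        # distances x<->a_i: {4,5,6,7} -> mean 5.5
        assert candidate_mean_distance(tree, "x", {"a1", "a2", "a3", "a4"}) \
            == pytest.approx(5.5)

    def test_candidate_in_accepted_rejected(self, basic_tree):
        with pytest.raises(ValidationError):
            candidate_mean_distance(basic_tree, "A", {"A", "B"})

    @pytest.mark.parametrize("seed", [3, 4])
    def test_candidate_mean_matches_oracle(self, seed):
        from conftest import patristic_oracle

        tree = synth.simulate_species_tree(8, seed)
        labels, mat = patristic_oracle(tree)
        idx = {l: i for i, l in enumerate(labels)}
        accepted = set(labels[:5])
        cand = labels[6]
        expect = np.mean([mat[idx[cand], idx[a]] for a in sorted(accepted)])
        assert candidate_mean_distance(tree, cand, accepted) == pytest.approx(expect)


def _bipartition_oracle(tree: Tree, group: set[str]) -> bool:
    """Edge enumeration: does any edge split exactly `group` from the rest?"""
    tips = set(tree.tip_names)
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == group or below == tips - group:
            return True
    return False


class TestCandidateClade:
    def test_explicit_bipartition(self):
        tree = Tree.from_newick("((c1:1,c2:1):1,(a1:1,a2:1):1);")
        assert is_candidate_clade(tree, {"c1", "c2"}) is True

    def test_split_candidates(self):
        tree = Tree.from_newick("((c1:1,a1:1):1,(c2:1,a2:1):1);")
        assert is_candidate_clade(tree, {"c1", "c2"}) is False

    def test_complement_side_of_root_counts(self):
        # {A,B} spans the root yet an edge separates it in the unrooted tree
        tree = Tree.from_newick("(A:1,(C:1,D:1):1,B:1);")
        assert is_candidate_clade(tree, {"C", "D"}) is True

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_agrees_with_edge_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = synth.simulate_species_tree(8, seed)
        tips = sorted(tree.tip_names)
        for _ in range(20):
            size = int(rng.integers(2, 7))
            group = set(rng.choice(tips, size=size, replace=False))
            assert is_candidate_clade(tree, group) == \
                _bipartition_oracle(tree, group)


class TestPlausibility:
    TAX = TaxonomyMap({
        "myriapod_x": ["Arthropoda", "Myriapoda"],
        "chelicerate_a": ["Arthropoda", "Chelicerata"],
        "human_a": ["Deuterostomia", "Vertebrata"],
        "daphnia_a": ["Arthropoda", "Pancrustacea"],
        "daphnia_b": ["Arthropoda", "Pancrustacea"],
    })

    def test_rank_controls_strictness(self):
        # the myriapod's nearest accepted tip is a chelicerate: fine at the
        # phylum rank, implausible at the class rank
        tree = Tree.from_newick(
            "((myriapod_x:1,chelicerate_a:1):1,(human_a:3,daphnia_a:3):1);")
        accepted = {"chelicerate_a", "human_a", "daphnia_a"}
        assert is_plausible(tree, "myriapod_x", accepted, self.TAX, rank=0)
        assert not is_plausible(tree, "myriapod_x", accepted, self.TAX, rank=1)

    def test_clustering_with_human_is_implausible(self):
        tree = Tree.from_newick(
            "((daphnia_b:1,human_a:1):1,(chelicerate_a:3,daphnia_a:3):1);")
        accepted = {"chelicerate_a", "human_a", "daphnia_a"}
        assert not is_plausible(tree, "daphnia_b", accepted, self.TAX, rank=0)

    def test_own_genus_neighbour_plausible_at_every_rank(self):
        tree = Tree.from_newick(
            "((daphnia_b:1,daphnia_a:1):1,(chelicerate_a:3,human_a:3):1);")
        accepted = {"chelicerate_a", "human_a", "daphnia_a"}
        for rank in (0, 1):
            assert is_plausible(tree, "daphnia_b", accepted, self.TAX, rank)

    def test_missing_taxonomy_entry_raises(self):
        tree = Tree.from_newick("((x:1,human_a:1):1,daphnia_a:2);")
        with pytest.raises(ValidationError):
            is_plausible(tree, "x", {"human_a", "daphnia_a"}, self.TAX, 0)


class TestRuleEngine:
    @pytest.mark.parametrize("scenario", rule_scenarios(),
                             ids=lambda s: s["name"])
    def test_each_rule_code(self, scenario):
        decisions = screen_family(scenario["msa"], ACCEPTED5,
                                  scenario["candidates"], scenario["taxonomy"],
                                  scenario["config"])
        got = {d.candidate_id: (d.rule, d.accepted) for d in decisions}
        assert got == scenario["expected"]

    @pytest.mark.parametrize("scenario", rule_scenarios(),
                             ids=lambda s: s["name"])
    def test_decision_totality_and_flags(self, scenario):
        decisions = screen_family(scenario["msa"], ACCEPTED5,
                                  scenario["candidates"], scenario["taxonomy"],
                                  scenario["config"])
        assert {d.candidate_id for d in decisions} == scenario["candidates"]
        for d in decisions:
            if d.accepted:
                assert d.rule in ACCEPTING_RULES
            assert d.flagged == (d.rule == "2c")

    @pytest.mark.parametrize("factor", [0.1, 1.0, 17.0])
    def test_scale_invariance(self, factor):
        # multiplying every branch length by c changes no rule outcome
        for scenario in rule_scenarios():
            cfg = scenario["config"]
            scaled_tree = Tree.from_newick(cfg.gene_tree.to_newick(),
                                           unit=cfg.gene_tree.unit)
            synth._scale_tree(scaled_tree, factor)
            scaled = ScreenConfig(gene_tree=scaled_tree)
            base = screen_family(scenario["msa"], ACCEPTED5,
                                 scenario["candidates"], scenario["taxonomy"],
                                 cfg)
            after = screen_family(scenario["msa"], ACCEPTED5,
                                  scenario["candidates"], scenario["taxonomy"],
                                  scaled)
            assert [(d.rule, d.accepted) for d in base] == \
                [(d.rule, d.accepted) for d in after]

    def test_small_family_routed_to_indeterminate(self, toy_msa):
        msa = Msa(list(toy_msa.records) + [SequenceRecord("cand", "MKVLIDHG")])
        decisions = screen_family(msa, {"s1", "s2", "s3"}, {"cand"},
                                  TaxonomyMap({}), ScreenConfig())
        assert decisions[0].rule == "indeterminate"
        assert not decisions[0].accepted

    def test_no_paralog_low_divergence_all_rule_1(self):
        # an ordinary new species with no duplication history lands in rule 1
        rng = np.random.default_rng(11)
        for _ in range(5):
            seed = int(rng.integers(2**31 - 1))
            species = synth.simulate_species_tree(10, seed)
            synth._scale_tree(species, 0.3 / synth._tree_depth(species))
            _, msa = synth.simulate_sequences(species, 300, seed + 1)
            cand = sorted(species.tip_names)[0]
            taxonomy = TaxonomyMap({t: ["all"] for t in species.tip_names})
            decisions = screen_family(msa, set(species.tip_names) - {cand},
                                      {cand}, taxonomy, ScreenConfig())
            assert decisions[0].rule == "1" and decisions[0].accepted


class TestMisalignment:
    def test_well_aligned_candidate(self, toy_msa):
        msa = place_candidate(toy_msa, SequenceRecord("new", "MKVLIDHG"))
        assert not is_misaligned(msa, "new")

    def test_overlong_candidate_misaligned(self, toy_msa):
        msa = place_candidate(
            toy_msa, SequenceRecord("new", "MKV" + "W" * 30 + "LIDHG"))
        assert is_misaligned(msa, "new")
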