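"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: patristic
distances come from root-path sums, Mk likelihoods and marginals from
explicit enumeration over all internal-node state assignments, and block
trimming from a plain column scan.
"""

import itertools

import numpy as np
import pytest

from paleoroute.mk_asr import mk_transition
from paleoroute.phylo_io import HabitatMatrix, Msa, SequenceRecord, Tree
from paleoroute.timescale import Chronogram
from paleoroute import synthetic_data as synth


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def patristic_oracle(tree: Tree) -> tuple[list, np.ndarray]:
    """Tip-to-tip distances by summing root paths: d(a,b) = da + db - 2*d(mrca)."""
    paths = {}
    for leaf in tree.dtree.leaf_node_iter():
        node, path = leaf, []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path
    depth = {}
    for node in tree.dtree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
    labels = sorted(paths)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            mrca = next(x for x in paths[a] if x in set(paths[b]))
            d = depth[paths[a][0]] + depth[paths[b][0]] - 2 * depth[mrca]
            mat[i, j] = mat[j, i] = d
    return labels, mat


def mk_loglik_oracle(chronogram: Chronogram, habitat: HabitatMatrix,
                     q: float) -> float:
    """Brute-force likelihood: sum over every internal-node state assignment."""
    nodes = list(chronogram.dtree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    states = habitat.alphabet
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        lik = 1.0 / k
        for node in nodes:
            if node.parent_node is None:
                continue
            P = mk_transition(q, node.edge.length or 0.0, k)
            ps = amap[node.parent_node]
            cs = (amap[node] if not node.is_leaf()
                  else idx[habitat.states[node.taxon.label]])
            lik *= P[ps, cs]
        total += lik
    return float(np.log(total)) if total > 0 else float("-inf")


def mk_marginals_oracle(chronogram: Chronogram, habitat: HabitatMatrix,
                        q: float) -> dict:
    """Brute-force per-internal-node marginals by enumeration."""
    nodes = list(chronogram.dtree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    states = habitat.alphabet
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    acc = {n: np.zeros(k) for n in internal}
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        lik = 1.0 / k
        for node in nodes:
            if node.parent_node is None:
                continue
            P = mk_transition(q, node.edge.length or 0.0, k)
            ps = amap[node.parent_node]
            cs = (amap[node] if not node.is_leaf()
                  else idx[habitat.states[node.taxon.label]])
            lik *= P[ps, cs]
        for n in internal:
            acc[n][amap[n]] += lik
    return {chronogram.node_label(n): v / v.sum() for n, v in acc.items()}


def trim_oracle(labels: list[str], min_block: int = 5) -> list[int]:
    """Brute-force block scan over column labels (0-based kept indices):
    maximal runs of conserved/highly_conserved columns, shrunk to their
    outermost highly_conserved columns, kept when >= min_block long."""
    kept = []
    i, n = 0, len(labels)
    while i < n:
        if labels[i] in ("conserved", "highly_conserved"):
            j = i
            while j < n and labels[j] in ("conserved", "highly_conserved"):
                j += 1
            run = list(range(i, j))
            while run and labels[run[0]] != "highly_conserved":
                run.pop(0)
            while run and labels[run[-1]] != "highly_conserved":
                run.pop()
            if len(run) >= min_block:
                kept.extend(run)
            i = j
        else:
            i += 1
    return kept


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def basic_tree() -> Tree:
    return Tree.from_newick("((A:1,B:2):1,C:3);")


@pytest.fixture
def toy_msa() -> Msa:
    return Msa([
        SequenceRecord("s1", "MKVLIDHG"),
        SequenceRecord("s2", "MKVLIEHG"),
        SequenceRecord("s3", "MKVMIDHG"),
        SequenceRecord("s4", "MRVLIDHG"),
    ])


def random_chronogram(n_tips: int, seed: int, depth: float = 50.0) -> Chronogram:
    tree = synth.simulate_species_tree(max(n_tips, 3), seed)
    synth._scale_tree(tree, depth / synth._tree_depth(tree))
    return Chronogram.from_newick(tree.to_newick())


# ---------------------------------------------------------------------------
# rule-engine scenarios (one per decision code)
# ---------------------------------------------------------------------------

def rule_scenarios():
    """Seven hand-built screening scenarios, one per rule code.

    The shared backbone places five accepted tips with pairwise patristic
    distances {2 x2, 4 x8}: mean 3.6, sample SD 0.8433, threshold 6.13. A
    candidate hanging at branch length X off the a5 cherry has mean distance
    X + 2.6 to the accepted set, so X = 1 is comfortably inside and X = 8
    far outside the threshold.
    """
    from paleoroute.orthology_screen import (
        ScreenConfig, TaxonomyMap, place_candidate,
    )

    accepted = {"a1", "a2", "a3", "a4", "a5"}
    seq = "MKVLIDHGMKVL"
    same_group = TaxonomyMap(
        {t: ["Panarthropoda"] for t in
         ["a1", "a2", "a3", "a4", "a5", "cand", "c1", "c2"]})

    def msa_for(ids):
        return Msa([SequenceRecord(i, seq) for i in ids])

    def tree_for(x):
        return Tree.from_newick(
            f"((a1:1,a2:1):1,(a3:1,a4:1):1,(a5:1,cand:{x}):1);",
            unit="substitutions_per_site")

    scenarios = []

    scenarios.append(dict(
        name="rule1_single_within_threshold",
        msa=msa_for(["a1", "a2", "a3", "a4", "a5", "cand"]),
        candidates={"cand"}, taxonomy=same_group,
        config=ScreenConfig(gene_tree=tree_for(1)),
        expected={"cand": ("1", True)},
    ))

    # rule 2a: an over-long candidate whose residues mostly land in
    # insertion columns, twice
    base = msa_for(["a1", "a2", "a3", "a4", "a5"])
    long_cand = SequenceRecord("cand", "WWWWCCCCWWWWCCCCWWWWCCCCWWWWCCCCWWWWCCCC")
    misaligned_msa = place_candidate(base, long_cand)
    scenarios.append(dict(
        name="rule2a_misaligned_after_retry",
        msa=misaligned_msa,
        candidates={"cand"}, taxonomy=same_group,
        config=ScreenConfig(gene_tree=tree_for(8)),
        expected={"cand": ("2a", False)},
    ))

    split_group = TaxonomyMap({**{t: ["Deuterostomia"] for t in accepted},
                               "cand": ["Panarthropoda"]})
    scenarios.append(dict(
        name="rule2b_distant_implausible",
        msa=msa_for(["a1", "a2", "a3", "a4", "a5", "cand"]),
        candidates={"cand"}, taxonomy=split_group,
        config=ScreenConfig(gene_tree=tree_for(8)),
        expected={"cand": ("2b", False)},
    ))

    scenarios.append(dict(
        name="rule2c_distant_plausible_flagged",
        msa=msa_for(["a1", "a2", "a3", "a4", "a5", "cand"]),
        candidates={"cand"}, taxonomy=same_group,
        config=ScreenConfig(gene_tree=tree_for(8)),
        expected={"cand": ("2c", True)},
    ))

    clade_tree = Tree.from_newick(
        "((a1:1,a2:1):1,(a3:1,a4:1):1,(a5:1,(c1:0.2,c2:0.6):1):1);",
        unit="substitutions_per_site")
    scenarios.append(dict(
        name="rule3a_candidate_clade_keep_shortest",
        msa=msa_for(["a1", "a2", "a3", "a4", "a5", "c1", "c2"]),
        candidates={"c1", "c2"}, taxonomy=same_group,
        config=ScreenConfig(gene_tree=clade_tree),
        expected={"c1": ("3a", True), "c2": ("3a", False)},
    ))

    non_clade_tree = Tree.from_newick(
        "((a1:1,a2:1):1,(a3:1,a4:1,c2:20):1,(a5:1,c1:1):1);",
        unit="substitutions_per_site")
    scenarios.append(dict(
        name="rule3b_exactly_one_within_threshold",
        msa=msa_for(["a1", "a2", "a3", "a4", "a5", "c1", "c2"]),
        candidates={"c1", "c2"}, taxonomy=same_group,
        config=ScreenConfig(gene_tree=non_clade_tree),
        expected={"c1": ("3b", True), "c2": ("3b", False)},
    ))

    far_tree = Tree.from_newick(
        "((a1:1,a2:1):1,(a3:1,a4:1,c2:20):1,(a5:1,c1:8):1);",
        unit="substitutions_per_site")
    scenarios.append(dict(
        name="rule3c_all_over_threshold",
        msa=msa_for(["a1", "a2", "a3", "a4", "a5", "c1", "c2"]),
        candidates={"c1", "c2"}, taxonomy=same_group,
        config=ScreenConfig(gene_tree=far_tree),
        expected={"c1": ("3c", False), "c2": ("3c", False)},
    ))
    return scenarios
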