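"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the study conditions the pipeline is built for: gene
families containing true orthologues plus planted in-/out-paralogs on
elongated branches, chronograms carrying fossil tips at their occurrence
ages, tip habitat states evolved forward under the symmetric Mk process, and
chronogram/substitution-tree pairs with a planted fraction of internal
branches sitting exactly at the median rate. Every generator is a pure
function of (config, seed).

Simplifications relative to real data: sequence evolution is a 20-state
symmetric (Poisson-style) substitution process with no rate heterogeneity
across sites and no indels, and the similarity-search E-value is a fixed
monotone surrogate map of pairwise difference, not a reimplementation of
real search statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ValidationError
from .mk_asr import mk_transition
from .phylo_io import (
    AMINO_ACIDS,
    DEFAULT_HABITAT_STATES,
    HabitatMatrix,
    HitRecord,
    Msa,
    SequenceRecord,
    Tree,
)
from .timescale import AGE_ATTR, Chronogram

logger = logging.getLogger(__name__)

ORTHOLOGUE = "orthologue"
IN_PARALOG = "in_paralog"
OUT_PARALOG = "out_paralog"

#: E-value surrogate map constants: E = 10^(2 - L * excess_identity), with
#: excess identity measured above the ~0.06 random amino-acid expectation,
#: clamped to [1e-180, 1e2]. Monotone non-decreasing in difference fraction.
EVALUE_RANDOM_IDENTITY = 0.06
EVALUE_MIN = 1e-180
EVALUE_MAX = 1e2


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generators (all rates >= 0, seed mandatory)."""

    seed: int
    n_taxa: int = 20
    seq_length: int = 200
    tree_depth_subs: float = 0.5  # root-to-tip depth of the scaled species tree
    duplication_rate: float = 0.05  # Poisson events per unit branch length
    out_elongation: float = 3.0  # planted out-paralog branch-length multiplier
    mk_q: float = 0.01  # habitat-change rate, per Myr
    n_fossil_tips: int = 4
    fossil_age_range: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("tree_depth_subs", "duplication_rate", "out_elongation",
                     "mk_q"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class FamilyTruth:
    """Ground truth of one simulated gene family."""

    labels: dict[str, str]  # tip -> orthologue / in_paralog / out_paralog
    species_tree: Tree
    duplications: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if ORTHOLOGUE not in self.labels.values():
            raise ValidationError("family must contain at least one orthologue")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_species_tree(n_taxa: int, seed: int) -> Tree:
    """Seeded Yule (pure-birth) tree with ``n_taxa`` tips, unit branch rate.

    Waiting times between speciations are exponential in the number of live
    lineages; a final waiting time is drawn after the last speciation so
    every pendant branch has strictly positive length. Tips are labelled
    ``t01, t02, ...`` in order of appearance. Branch lengths are unitless.
    """
    if n_taxa < 3:
        raise ValidationError("need n_taxa >= 3")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("origin", "children", "label", "length")

        def __init__(self, origin):
            self.origin = origin
            self.children = []
            self.label = None
            self.length = 0.0

    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        node.length = t - node.origin
        kids = [_N(t), _N(t)]
        node.children = kids
        active[i] = kids[0]
        active.append(kids[1])
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t - node.origin

    counter = [0]

    def to_newick(node) -> str:
        if not node.children:
            counter[0] += 1
            return f"t{counter[0]:02d}:{node.length:.10f}"
        inner = ",".join(to_newick(c) for c in node.children)
        return f"({inner}):{node.length:.10f}"

    text = "(" + ",".join(to_newick(c) for c in root.children) + ");"
    return Tree.from_newick(text, unit="unitless")


def _scale_tree(tree: Tree, factor: float) -> None:
    for edge in tree.dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor


def _tree_depth(tree: Tree) -> float:
    depth = 0.0
    for lf in tree.dtree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth = max(depth, d)
    return depth


def _copy_subtree(node: dendropy.Node, factor: float, suffix: str,
                  tns: dendropy.TaxonNamespace) -> dendropy.Node:
    new = dendropy.Node()
    new.edge.length = (node.edge.length or 0.0) * factor
    if node.is_leaf():
        taxon = dendropy.Taxon(label=node.taxon.label + suffix)
        tns.add_taxon(taxon)
        new.taxon = taxon
    for child in node.child_nodes():
        new.add_child(_copy_subtree(child, factor, suffix, tns))
    return new


def _graft_duplication(dtree: dendropy.Tree, head: dendropy.Node, u: float,
                       factor: float, suffix: str) -> None:
    """Split the edge above ``head`` at fraction ``u`` of its length and
    attach a (scaled) copy of the subtree below the split point."""
    parent = head.parent_node
    length = head.edge.length or 0.0
    mid = dendropy.Node()
    parent.remove_child(head)
    parent.add_child(mid)
    mid.edge.length = u * length
    head.edge.length = (1 - u) * length
    mid.add_child(head)
    copy = _copy_subtree(head, factor, suffix, dtree.taxon_namespace)
    mid.add_child(copy)


def simulate_gene_family(species_tree: Tree, config: SimConfig
                         ) -> tuple[Tree, FamilyTruth]:
    """Gene tree = species tree plus Poisson gene duplications.

    Duplication events fall on edges with probability proportional to edge
    length, at a uniform relative position. A duplication on an internal
    edge copies a multi-species subtree — an out-paralog family — and the
    copy's branch lengths are multiplied by ``out_elongation`` so planted
    out-paralogs overshoot the mean + 3 SD screening threshold at default
    divergence. Duplications on pendant edges yield lineage-specific
    in-paralogs (no elongation). Copy tips are suffixed ``_dK``.
    """
    rng = np.random.default_rng(config.seed)
    gene = species_tree.clone()
    edges = [e for e in gene.dtree.preorder_edge_iter()
             if e.head_node.parent_node is not None and (e.length or 0) > 0]
    lengths = np.array([e.length for e in edges])
    total = float(lengths.sum())
    n_events = rng.poisson(config.duplication_rate * total)
    labels = {t: ORTHOLOGUE for t in species_tree.tip_names}
    dups: list[tuple[str, float]] = []
    for k in range(1, n_events + 1):
        edges = [e for e in gene.dtree.preorder_edge_iter()
                 if e.head_node.parent_node is not None and (e.length or 0) > 0
                 and not _is_copy(e.head_node)]
        lengths = np.array([e.length for e in edges])
        edge = edges[int(rng.choice(len(edges), p=lengths / lengths.sum()))]
        u = float(rng.uniform())
        internal = not edge.head_node.is_leaf()
        factor = config.out_elongation if internal else 1.0
        suffix = f"_d{k}"
        tips_below = [l.taxon.label for l in edge.head_node.leaf_iter()]
        _graft_duplication(gene.dtree, edge.head_node, u, factor, suffix)
        kind = OUT_PARALOG if internal else IN_PARALOG
        for t in tips_below:
            labels[t + suffix] = kind
        dups.append(("{" + ",".join(sorted(tips_below)) + "}", u))
    return gene, FamilyTruth(labels, species_tree, dups)


def _is_copy(node: dendropy.Node) -> bool:
    return any("_d" in l.taxon.label for l in node.leaf_iter())


def plant_out_paralog(species_tree: Tree, config: SimConfig,
                      stem_fraction: float = 0.25) -> tuple[Tree, FamilyTruth]:
    """Gene tree with one out-paralog duplication preceding the family root.

    This is the canonical out-paralog history: the gene duplicated a stem's
    length (``stem_fraction`` of the tree depth) before the first speciation,
    so every species carries an orthologous copy and a ``_d1`` paralogous
    copy. The paralogous subtree's branch lengths (stem included) are
    multiplied by ``out_elongation``, which puts every planted paralog far
    beyond the mean + 3 SD screening threshold by construction: its mean
    distance to the accepted set exceeds four tree depths, while the
    threshold cannot reach three.
    """
    gene = species_tree.clone()
    dtree = gene.dtree
    old_root = dtree.seed_node
    tau = stem_fraction * _tree_depth(species_tree)
    copy = _copy_subtree(old_root, config.out_elongation, "_d1",
                         dtree.taxon_namespace)
    copy.edge.length = config.out_elongation * tau
    new_root = dendropy.Node()
    new_root.add_child(old_root)
    old_root.edge.length = tau
    new_root.add_child(copy)
    dtree.seed_node = new_root
    labels = {t: ORTHOLOGUE for t in species_tree.tip_names}
    for t in species_tree.tip_names:
        labels[t + "_d1"] = OUT_PARALOG
    truth = FamilyTruth(labels, species_tree, [("pre-root", stem_fraction)])
    return gene, truth


# ---------------------------------------------------------------------------
# sequences and hits
# ---------------------------------------------------------------------------

def p_identical(distance: float) -> float:
    """Probability two sites separated by path length ``d`` carry the same
    residue under the 20-state symmetric model (total rate 1 per unit
    length): ``1/20 + (19/20) exp(-20 d / 19)``."""
    return float(1 / 20 + (19 / 20) * np.exp(-20.0 * distance / 19.0))


def simulate_sequences(tree: Tree, length: int, seed: int
                       ) -> tuple[list[SequenceRecord], Msa]:
    """One sequence per tip, evolved site-independently down the tree.

    Substitutions follow the 20-state symmetric model with expected number
    of substitutions per site equal to the branch length. There are no
    indels, so the returned records double as the true alignment.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root_seq = rng.integers(0, 20, size=length)
    seqs: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            seqs[node] = root_seq
            continue
        b = node.edge.length or 0.0
        parent_seq = seqs[node.parent_node]
        stay = rng.uniform(size=length) < p_identical(b)
        child = parent_seq.copy()
        changed = ~stay
        if changed.any():
            # uniform among the 19 alternative residues
            shift = rng.integers(1, 20, size=int(changed.sum()))
            child[changed] = (parent_seq[changed] + shift) % 20
        seqs[node] = child
    records = [
        SequenceRecord(lf.taxon.label, aa[seqs[lf]].tobytes().decode())
        for lf in tree.dtree.leaf_node_iter()
    ]
    return records, Msa(records)


def difference_fraction(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        raise ValidationError("empty sequences")
    return sum(x != y for x, y in zip(a[:n], b[:n])) / n


def surrogate_evalue(diff_fraction: float, length: int) -> float:
    """Deterministic, documented E-value surrogate.

    ``E = 10 ** (2 - L * max(0, identity - 0.06))`` clamped to
    [1e-180, 100]: identical sequences reach the floor, random sequences
    (identity near the 1/20-ish background) sit at 100, and the map is
    monotone non-decreasing in the difference fraction. It drives the
    screening prefilter; it does not claim to reproduce real search
    statistics.
    """
    excess = max(0.0, (1.0 - diff_fraction) - EVALUE_RANDOM_IDENTITY)
    return float(np.clip(10.0 ** (2.0 - length * excess), EVALUE_MIN, EVALUE_MAX))


def simulate_hits(sequences: list[SequenceRecord], orthologue_ids: set[str],
                  seed: int = 0) -> list[HitRecord]:
    """Hit table of every sequence (query) against every orthologue (subject).

    E-values come from the deterministic surrogate map, so the same inputs
    always give the same table; ``seed`` is accepted for interface symmetry
    with the stochastic generators.
    """
    del seed  # the surrogate map is deterministic
    by_id = {r.id: r for r in sequences}
    hits = []
    for rec in sequences:
        for oid in sorted(orthologue_ids):
            if oid == rec.id:
                continue
            p = difference_fraction(rec.ungapped(), by_id[oid].ungapped())
            hits.append(HitRecord(rec.id, oid,
                                  surrogate_evalue(p, min(len(rec.ungapped()),
                                                          len(by_id[oid].ungapped())))))
    return hits


# ---------------------------------------------------------------------------
# habitat evolution on chronograms
# ---------------------------------------------------------------------------

def simulate_mk_tips(chronogram: Chronogram, q: float, seed: int,
                     states: tuple[str, ...] = DEFAULT_HABITAT_STATES,
                     root_state: str | None = None) -> HabitatMatrix:
    """Evolve tip states forward under Mk(q) along the chronogram.

    The root state is uniform unless ``root_state`` pins it (useful for
    recovery experiments). Fossil tips simply receive the state of their
    lineage at their occurrence age, because the chronogram's branch
    durations already stop there.
    """
    if q < 0:
        raise ValidationError("q must be >= 0")
    rng = np.random.default_rng(seed)
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    node_state: dict[dendropy.Node, int] = {}
    assignments: dict[str, str] = {}
    ages: dict[str, float] = {}
    for node in chronogram.dtree.preorder_node_iter():
        if node.parent_node is None:
            node_state[node] = (index[root_state] if root_state is not None
                                else int(rng.integers(k)))
        else:
            parent = node_state[node.parent_node]
            P = mk_transition(q, node.edge.length or 0.0, k)
            node_state[node] = int(rng.choice(k, p=P[parent]))
        if node.is_leaf():
            assignments[node.taxon.label] = states[node_state[node]]
            ages[node.taxon.label] = float(getattr(node, AGE_ATTR, 0.0))
    return HabitatMatrix(assignments, ages, states)


# ---------------------------------------------------------------------------
# end-to-end fixtures
# ---------------------------------------------------------------------------

def make_branchiopod_like_case(seed: int) -> tuple[Chronogram, HabitatMatrix]:
    """A ~25-tip chronogram with four fossil tips plus a habitat matrix,
    emulating a total-group crustacean habitat reconstruction.

    The topology is a seeded Yule tree of 21 extant tips scaled to a
    Cambrian-aged root, with four fossil tips grafted on: one deep Cambrian
    marine fossil branching below everything else (a Rehbachiella-like
    stem-group tip), two Early Devonian freshwater fossils and one
    Triassic–Jurassic freshwater fossil nested inside the extant radiation.
    Extant tips are mostly freshwater with a few brackish and one marine,
    so all three states are present.
    """
    rng = np.random.default_rng(seed)
    extant = simulate_species_tree(21, seed=int(rng.integers(2**31 - 1)))
    _scale_tree(extant, 440.0 / _tree_depth(extant))
    newick = extant.to_newick()
    # graft the deep marine fossil as sister to the whole extant clade
    inner = newick.rstrip(";").rstrip()
    fossil_ages = {"fossil_cambrian": 505.0, "fossil_devonian_a": 408.0,
                   "fossil_devonian_b": 406.0, "fossil_triassic": 220.0}
    root_age = 520.0
    # extant clade root sits at 440 Ma -> stem of 80 Myr; Cambrian fossil tip
    # hangs from the root with duration root_age - tip age
    text = (f"({inner}:80.0,fossil_cambrian:{root_age - 505.0});")
    tree = Tree.from_newick(text, unit="Myr")
    # graft the younger freshwater fossils onto random internal extant edges
    internal = [
        n for n in tree.dtree.preorder_node_iter()
        if n.parent_node is not None and not n.is_leaf()
        and not any(l.taxon.label.startswith("fossil") for l in n.leaf_iter())
    ]
    tip_ages = {t: 0.0 for t in extant.tip_names}
    tip_ages["fossil_cambrian"] = 505.0
    for name in ("fossil_devonian_a", "fossil_devonian_b", "fossil_triassic"):
        age = fossil_ages[name]
        depths = _node_depths(tree)
        # the attach point must fall on the host's edge and above the fossil age
        host_pool = [
            n for n in internal
            if (n.edge.length or 0) > 1.0
            and root_age - depths[n.parent_node] > age + 1.0
        ]
        host = host_pool[int(rng.integers(len(host_pool)))]
        node_age = root_age - depths[host]
        parent_age = root_age - depths[host.parent_node]
        attach_age = (max(node_age, age) + parent_age) / 2.0
        _graft_fossil(tree.dtree, host, attach_age, node_age, name, age)
        internal = [n for n in internal if n is not host]
        tip_ages[name] = age
    chrono = Chronogram.from_newick(tree.to_newick(), tip_ages=tip_ages)

    states: dict[str, str] = {}
    extant_names = sorted(extant.tip_names)
    brackish = set(extant_names[:2])
    marine_extant = {extant_names[2]}
    for t in extant_names:
        states[t] = ("brackish" if t in brackish
                     else "marine" if t in marine_extant else "freshwater")
    states["fossil_cambrian"] = "marine"
    states["fossil_devonian_a"] = "freshwater"
    states["fossil_devonian_b"] = "freshwater"
    states["fossil_triassic"] = "freshwater"
    matrix = HabitatMatrix(states, dict(tip_ages))
    return chrono, matrix


def _node_depths(tree: Tree) -> dict[dendropy.Node, float]:
    depths = {}
    for node in tree.dtree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = 0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
    return depths


def _graft_fossil(dtree: dendropy.Tree, host: dendropy.Node, attach_age: float,
                  host_age: float, name: str, tip_age: float) -> None:
    """Insert a fossil tip on the edge above ``host`` at ``attach_age`` Ma."""
    parent = host.parent_node
    mid = dendropy.Node()
    parent.remove_child(host)
    parent.add_child(mid)
    mid.edge.length = host.edge.length - (attach_age - host_age)
    host.edge.length = attach_age - host_age
    mid.add_child(host)
    taxon = dendropy.Taxon(label=name)
    dtree.taxon_namespace.add_taxon(taxon)
    tip = dendropy.Node(taxon=taxon)
    tip.edge.length = attach_age - tip_age
    mid.add_child(tip)


def make_rate_diag_case(seed: int, frac_at_median: float = 0.645,
                        n_tips: int = 202, depth: float = 500.0,
                        base_rate: float = 0.01, rootward: bool = True,
                        rate_sd: float = 0.5
                        ) -> tuple[Chronogram, Tree]:
    """A chronogram/substitution-tree pair with a planted fraction of
    internal branches at exactly the median rate.

    ``round(frac_at_median * n_internal)`` internal branches get rate
    ``base_rate`` (the tree-wide median, since the fraction exceeds one
    half); the rest draw lognormal rates around it. With ``rootward`` the
    at-median branches are the oldest by midpoint age (emulating a clock
    that was never relaxed near the root); otherwise they are a uniform
    random subset, which is the null configuration for the clustering test.
    A rooted Yule tree with ``n_tips`` tips has ``n_tips - 2`` internal
    non-root branches, so the default 202 tips make the 0.645 fraction
    exact (129 of 200).
    """
    if not 0.5 < frac_at_median <= 1.0:
        raise ValidationError("frac_at_median must be in (0.5, 1] so the "
                              "planted value is the median")
    rng = np.random.default_rng(seed)
    tree = simulate_species_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
    _scale_tree(tree, depth / _tree_depth(tree))
    chrono = Chronogram.from_newick(tree.to_newick())

    internal = [n for n in chrono.dtree.preorder_node_iter()
                if n.parent_node is not None and not n.is_leaf()]
    n_internal = len(internal)
    k = int(round(frac_at_median * n_internal))

    def midpoint(node):
        return (getattr(node.parent_node, AGE_ATTR) + getattr(node, AGE_ATTR)) / 2

    if rootward:
        chosen = set(sorted(internal, key=midpoint, reverse=True)[:k])
    else:
        idx = rng.choice(n_internal, size=k, replace=False)
        chosen = {internal[i] for i in idx}

    subs = Tree.from_newick(chrono.to_newick(), unit="substitutions_per_site")
    subs_map = _clade_lookup(subs)
    for node in chrono.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node in chosen:
            rate = base_rate
        else:
            rate = base_rate * float(np.exp(rng.normal(0.0, rate_sd)))
            if abs(rate - base_rate) < 1e-5 * base_rate:
                rate = base_rate * 1.01
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        subs_map[leaves].edge.length = rate * node.edge.length
    return chrono, subs


def _clade_lookup(tree: Tree) -> dict[frozenset[str], dendropy.Node]:
    out = {}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        out[frozenset(l.taxon.label for l in node.leaf_iter())] = node
    return out


# ---------------------------------------------------------------------------
# screening validation harness
# ---------------------------------------------------------------------------

def screening_validation(n_families: int = 50, seed: int = 0,
                         n_taxa: int = 20, out_elongation: float = 3.0
                         ) -> dict[str, float]:
    """Precision/recall of orthologue recovery on families with planted
    out-paralogs.

    Each family is a scaled Yule species tree; one species is the newly
    added candidate and contributes its true orthologue plus one planted,
    3x-elongated out-paralog copy. The rule engine runs on the generator's
    true gene tree (the decision rules consume only patristic distances, so
    any tree backend is interchangeable). Returns precision and recall over
    true orthologues and the rejection rate of planted out-paralogs.
    """
    from .orthology_screen import ScreenConfig, TaxonomyMap, screen_family

    rng = np.random.default_rng(seed)
    tp = fp = fn = 0
    paralogs_rejected = paralogs_total = 0
    for _ in range(n_families):
        fam_seed = int(rng.integers(2**31 - 1))
        config = SimConfig(seed=fam_seed, n_taxa=n_taxa,
                           out_elongation=out_elongation)
        species = simulate_species_tree(n_taxa, fam_seed)
        _scale_tree(species, config.tree_depth_subs / _tree_depth(species))
        candidate = sorted(species.tip_names)[int(rng.integers(n_taxa))]
        gene, truth = plant_out_paralog(species, config)
        accepted = set(species.tip_names) - {candidate}
        candidates = {t for t in gene.tip_names
                      if t == candidate or t.startswith(candidate + "_d")}
        seqs, msa = simulate_sequences(gene, length=60,
                                       seed=int(rng.integers(2**31 - 1)))
        taxonomy = TaxonomyMap({t: ["Panarthropoda"] for t in gene.tip_names})
        decisions = screen_family(
            msa, accepted, candidates, taxonomy,
            ScreenConfig(gene_tree=gene))
        for d in decisions:
            is_true_orth = truth.labels.get(d.candidate_id) == ORTHOLOGUE
            if is_true_orth:
                tp += d.accepted
                fn += not d.accepted
            else:
                paralogs_total += 1
                paralogs_rejected += not d.accepted
                fp += d.accepted
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "paralog_rejection_rate": (paralogs_rejected / paralogs_total
                                   if paralogs_total else float("nan")),
        "n_families": float(n_families),
    }
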