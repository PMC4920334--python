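"""Candidate-orthologue screening by patristic-distance statistics.

A gene family carries a set of previously accepted orthologues. New candidate
sequences (typically from one newly added species) are prefiltered by
similarity-search E-value, placed into the existing alignment, and judged on
a gene tree by a small decision table:

* a single candidate whose mean patristic distance to the accepted set lies
  within ``mean + 3*sd`` of the accepted pairwise distances is accepted
  (rule 1);
* a single distant candidate is first checked for misalignment (one
  realignment retry; still-misaligned candidates are rejected under rule 2a),
  then for phylogenetic plausibility: an implausibly placed candidate is
  rejected as a likely paralogue (rule 2b), a plausibly placed one is
  accepted but flagged (rule 2c);
* multiple candidates forming a clade with acceptable average distance keep
  only the member with the shortest terminal branch (rule 3a); when they do
  not form a clade and exactly one is within the threshold, that one is kept
  if plausibly placed (rule 3b); when all exceed the threshold, all are
  rejected (rule 3c). Configurations outside the table are reported as
  ``indeterminate`` for manual review.

All distance statistics are backend-agnostic: the gene tree may come from
the built-in neighbor-joining backend or be supplied externally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import InsufficientReferenceError, ValidationError
from .phylo_io import HitRecord, Msa, SequenceRecord, Tree

logger = logging.getLogger(__name__)

ACCEPTING_RULES = frozenset({"1", "2c", "3a", "3b"})

#: 20-state saturation ceiling for the corrected distance, in subs/site.
MAX_DISTANCE = 10.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSummary:
    """Pairwise patristic-distance statistics of the accepted orthologues.

    ``threshold = mean + sd_multiplier * sd`` is the acceptance ceiling for a
    candidate's mean distance; ``sd`` is the sample (n-1) standard deviation.
    """

    mean: float
    sd: float
    threshold: float
    n_pairs: int

    def __post_init__(self):
        if self.threshold < self.mean:
            raise ValidationError("threshold below mean")


@dataclass(frozen=True)
class CandidateDecision:
    """The audit record of one candidate sequence's fate."""

    candidate_id: str
    rule: str  # one of 1, 2a, 2b, 2c, 3a, 3b, 3c, indeterminate
    accepted: bool
    flagged: bool = False
    candidate_mean_distance: float = float("nan")
    threshold_used: float = float("nan")
    notes: str = ""

    def __post_init__(self):
        if self.accepted and self.rule not in ACCEPTING_RULES:
            raise ValidationError(f"rule {self.rule!r} cannot accept")
        if self.flagged and self.rule != "2c":
            raise ValidationError("only rule 2c decisions are flagged")


@dataclass
class TaxonomyMap:
    """Taxon label -> ordered group labels from coarse to fine."""

    groups: dict[str, list[str]]

    def label(self, taxon: str, rank: int) -> str:
        if taxon not in self.groups:
            raise ValidationError(f"taxon {taxon!r} missing from taxonomy map")
        path = self.groups[taxon]
        if not 0 <= rank < len(path):
            raise ValidationError(
                f"rank {rank} out of range for taxon {taxon!r} (depth {len(path)})"
            )
        return path[rank]

    @classmethod
    def from_table(cls, path: str | Path) -> "TaxonomyMap":
        """Tab-separated: taxon<TAB>group,group,... (coarse to fine)."""
        groups: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, _, rest = line.partition("\t")
            groups[taxon.strip()] = [g.strip() for g in rest.split(",") if g.strip()]
        return cls(groups)


@dataclass
class ScreenConfig:
    """Tunables of the screening rule engine."""

    evalue_threshold: float = 1e-20
    sd_multiplier: float = 3.0
    min_accepted: int = 4
    plausibility_rank: int = 0
    gamma_shape: float = 1.0
    misaligned_min_fraction: float = 0.5
    column_occupancy_fraction: float = 0.5
    gene_tree: Tree | None = None  # externally computed tree overrides NJ


# ---------------------------------------------------------------------------
# E-value prefilter
# ---------------------------------------------------------------------------

def filter_hits(hits: Iterable[HitRecord], threshold: float = 1e-20) -> set[str]:
    """Queries with at least one hit with E-value strictly below ``threshold``."""
    return {h.query for h in hits if h.evalue < threshold}


# ---------------------------------------------------------------------------
# candidate placement into the existing alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def place_candidate(msa: Msa, candidate: SequenceRecord,
                    reference_rank: int = 0) -> Msa:
    """Insert ``candidate`` into ``msa`` by pairwise alignment to a reference row.

    The candidate's ungapped sequence is globally aligned (BLOSUM62) against
    the highest-scoring existing row (``reference_rank`` selects lower-ranked
    references for realignment retries). Candidate insertions relative to the
    reference become new all-gap columns; existing rows are otherwise
    unchanged.
    """
    seq = candidate.ungapped()
    if not seq:
        raise ValidationError(f"candidate {candidate.id!r} has no non-gap residues")
    aligner = _make_aligner()
    scores = [(aligner.score(row.ungapped(), seq), i) for i, row in enumerate(msa)]
    scores.sort(key=lambda t: (-t[0], t[1]))
    rank = min(reference_rank, len(scores) - 1)
    ref = msa[scores[rank][1]]
    ref_seq = ref.ungapped()
    # column index of each non-gap residue of the reference row
    ref_cols = [j for j, c in enumerate(ref.residues) if c != "-"]
    aln = aligner.align(ref_seq, seq)[0]
    idx = aln.indices  # 2 x L, -1 marks a gap

    cand_at_col: dict[int, str] = {}
    insertions: dict[int, list[str]] = {}  # keyed by msa column to insert AFTER (-1 = front)
    last_col = -1
    for t_i, q_i in zip(idx[0], idx[1]):
        if t_i >= 0 and q_i >= 0:
            last_col = ref_cols[t_i]
            cand_at_col[last_col] = seq[q_i]
        elif t_i >= 0:
            last_col = ref_cols[t_i]
        else:  # insertion in candidate
            insertions.setdefault(last_col, []).append(seq[q_i])

    def rebuild(residues: str, cand: bool) -> str:
        out = list(insertions.get(-1, []) if cand else "-" * len(insertions.get(-1, [])))
        for j, c in enumerate(residues):
            out.append(cand_at_col.get(j, "-") if cand else c)
            ins = insertions.get(j, [])
            out.extend(ins if cand else "-" * len(ins))
        return "".join(out)

    template = "-" * msa.n_columns
    rows = [SequenceRecord(r.id, rebuild(r.residues, cand=False), r.taxon) for r in msa]
    rows.append(SequenceRecord(candidate.id, rebuild(template, cand=True), candidate.taxon))
    return Msa(rows)


def remove_row(msa: Msa, seq_id: str) -> Msa:
    rows = [r for r in msa if r.id != seq_id]
    if len(rows) == len(msa.records):
        raise KeyError(seq_id)
    return Msa(rows)


# ---------------------------------------------------------------------------
# distances and gene trees
# ---------------------------------------------------------------------------

def pairwise_distance(a: str, b: str, gamma_shape: float = 1.0) -> float:
    """Gamma-corrected 20-state distance between two aligned rows.

    The proportion of differing sites p is measured over columns where both
    rows are non-gap; the correction inverts the 20-state symmetric
    substitution model with gamma-distributed rate variation of shape ``a``:
    ``d = (19/20) * a * ((1 - 20 p / 19)^(-1/a) - 1)``. Saturated pairs are
    capped at :data:`MAX_DISTANCE`.
    """
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        raise ValidationError("no overlapping non-gap columns")
    p = sum(x != y for x, y in both) / len(both)
    if p >= 19 / 20:
        return MAX_DISTANCE
    d = (19 / 20) * gamma_shape * ((1 - 20 * p / 19) ** (-1 / gamma_shape) - 1)
    return min(float(d), MAX_DISTANCE)


def nj_tree(labels: Sequence[str], dmatrix: np.ndarray,
            unit: str = "substitutions_per_site") -> Tree:
    """Neighbor-joining tree from a distance matrix.

    Exact on additive inputs. Negative NJ branch-length estimates are
    clamped to zero.
    """
    dm = DistanceMatrix(dmatrix, ids=list(labels))
    tnode = _skbio_nj(dm)
    buf = StringIO()
    tnode.write(buf)
    import dendropy

    dtree = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                              preserve_underscores=True,
                              suppress_internal_node_taxa=True)
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return Tree(dtree, unit=unit)


def build_gene_tree(msa: Msa, gamma_shape: float = 1.0) -> Tree:
    """NJ gene tree on gamma-corrected distances (deterministic).

    An externally computed maximum-likelihood tree may be used instead by
    passing it to :func:`screen_family` via :class:`ScreenConfig`.
    """
    if len(msa) < 3:
        raise ValidationError("gene tree needs >= 3 sequences")
    n = len(msa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = pairwise_distance(
                    msa[i].residues, msa[j].residues, gamma_shape
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"rows {msa[i].id!r} and {msa[j].id!r}: {exc}"
                ) from exc
    return nj_tree(msa.ids, D)


def patristic_matrix(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Sorted tip labels and the symmetric tip-to-tip path-length matrix."""
    return tree.patristic_matrix()


class _DistanceTable:
    """Label-indexed view over a patristic matrix."""

    def __init__(self, tree: Tree):
        labels, mat = tree.patristic_matrix()
        self.index = {lab: i for i, lab in enumerate(labels)}
        self.mat = mat

    def __call__(self, a: str, b: str) -> float:
        return float(self.mat[self.index[a], self.index[b]])


def distance_summary(tree: Tree, accepted: set[str],
                     sd_multiplier: float = 3.0,
                     min_accepted: int = 4) -> DistanceSummary:
    """Mean, sample SD and acceptance threshold over all unordered pairs of
    accepted tips. Requires at least ``min_accepted`` accepted orthologues."""
    if len(accepted) < min_accepted:
        raise InsufficientReferenceError(
            f"{len(accepted)} accepted orthologues < required {min_accepted}"
        )
    dist = _DistanceTable(tree)
    acc = sorted(accepted)
    pairs = [dist(a, b) for i, a in enumerate(acc) for b in acc[i + 1:]]
    mean = float(np.mean(pairs))
    sd = float(np.std(pairs, ddof=1))
    return DistanceSummary(mean, sd, mean + sd_multiplier * sd, len(pairs))


def candidate_mean_distance(tree: Tree, candidate: str, accepted: set[str]) -> float:
    """Arithmetic mean of patristic distances candidate <-> each accepted tip."""
    if candidate in accepted:
        raise ValidationError(f"candidate {candidate!r} is in the accepted set")
    dist = _DistanceTable(tree)
    return float(np.mean([dist(candidate, a) for a in sorted(accepted)]))


def is_candidate_clade(tree: Tree, candidates: set[str]) -> bool:
    """True iff one edge of the unrooted tree separates exactly the candidate
    set from all other tips (root placement irrelevant)."""
    if len(candidates) < 2:
        raise ValidationError("clade test needs >= 2 candidates")
    tips = set(tree.tip_names)
    missing = candidates - tips
    if missing:
        raise ValidationError(f"candidates not in tree: {sorted(missing)}")

    def is_rooted_clade(group: set[str]) -> bool:
        mrca = tree.dtree.mrca(taxon_labels=list(group))
        leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
        return leaves == group

    # an unrooted bipartition exists iff the set or its complement is a
    # rooted clade under the current rooting
    return is_rooted_clade(candidates) or is_rooted_clade(tips - candidates)


def is_plausible(tree: Tree, candidate: str, accepted: set[str],
                 taxonomy: TaxonomyMap, rank: int = 0) -> bool:
    """Nearest-accepted-neighbour taxonomy agreement at ``rank``.

    Automates visual plausibility inspection: the candidate is plausibly
    placed when its nearest accepted tip (by patristic distance) belongs to
    the same taxonomy group at the configured rank. Coarse ranks tolerate
    distant-but-sane placements; finer ranks demand closer agreement.
    """
    dist = _DistanceTable(tree)
    nearest = min(sorted(accepted), key=lambda a: (dist(candidate, a), a))
    return taxonomy.label(candidate, rank) == taxonomy.label(nearest, rank)


# ---------------------------------------------------------------------------
# misalignment heuristic (rule 2a)
# ---------------------------------------------------------------------------

def is_misaligned(msa: Msa, candidate_id: str,
                  min_fraction: float = 0.5,
                  occupancy_fraction: float = 0.5) -> bool:
    """A candidate row is misaligned when fewer than ``min_fraction`` of its
    non-gap residues fall in columns occupied by at least
    ``occupancy_fraction`` of the other rows."""
    cand = msa[candidate_id]
    others = [r for r in msa if r.id != candidate_id]
    if not others:
        raise ValidationError("no reference rows to assess alignment against")
    in_occupied = total = 0
    for j, c in enumerate(cand.residues):
        if c == "-":
            continue
        total += 1
        occ = sum(r.residues[j] != "-" for r in others) / len(others)
        if occ >= occupancy_fraction:
            in_occupied += 1
    return (in_occupied / total) < min_fraction


# ---------------------------------------------------------------------------
# the rule engine
# ---------------------------------------------------------------------------

def _pendant_length(tree: Tree, tip: str) -> float:
    return float(tree.find_tip(tip).edge.length or 0.0)


def screen_family(msa: Msa, accepted: set[str], candidates: set[str],
                  taxonomy: TaxonomyMap,
                  config: ScreenConfig | None = None) -> list[CandidateDecision]:
    """Run the decision table over all candidates of one gene family.

    ``msa`` must contain rows for every accepted and candidate id. Every
    candidate receives exactly one :class:`CandidateDecision`; a decision is
    accepting only under rules 1, 2c, 3a and 3b. Clade-mates passed over by
    rule 3a and over-threshold co-candidates in a rule-3b family share the
    scenario's rule code with ``accepted=False`` and an explanatory note.
    """
    config = config or ScreenConfig()
    if accepted & candidates:
        raise ValidationError("candidate and accepted sets overlap")
    missing = (accepted | candidates) - set(msa.ids)
    if missing:
        raise ValidationError(f"ids missing from alignment: {sorted(missing)}")

    if len(accepted) < config.min_accepted:
        return [
            CandidateDecision(c, "indeterminate", False,
                              notes=f"only {len(accepted)} accepted orthologues "
                                    f"(< {config.min_accepted}); manual review")
            for c in sorted(candidates)
        ]

    tree = config.gene_tree or build_gene_tree(msa, config.gamma_shape)
    summary = distance_summary(tree, accepted, config.sd_multiplier,
                               config.min_accepted)
    mean_d = {c: candidate_mean_distance(tree, c, accepted) for c in candidates}

    if len(candidates) == 1:
        return [_screen_single(msa, next(iter(candidates)), accepted, taxonomy,
                               config, tree, summary)]
    return _screen_multiple(candidates, accepted, taxonomy, config, tree,
                            summary, mean_d)


def _screen_single(msa: Msa, cand: str, accepted: set[str],
                   taxonomy: TaxonomyMap, config: ScreenConfig,
                   tree: Tree, summary: DistanceSummary) -> CandidateDecision:
    d = candidate_mean_distance(tree, cand, accepted)
    if d <= summary.threshold:
        return CandidateDecision(cand, "1", True, candidate_mean_distance=d,
                                 threshold_used=summary.threshold)
    notes = []
    if is_misaligned(msa, cand, config.misaligned_min_fraction,
                     config.column_occupancy_fraction):
        # one realignment retry against the second-best reference row
        cand_rec = msa[cand]
        realigned = place_candidate(remove_row(msa, cand),
                                    SequenceRecord(cand_rec.id,
                                                   cand_rec.ungapped(),
                                                   cand_rec.taxon),
                                    reference_rank=1)
        if is_misaligned(realigned, cand, config.misaligned_min_fraction,
                         config.column_occupancy_fraction):
            return CandidateDecision(
                cand, "2a", False, candidate_mean_distance=d,
                threshold_used=summary.threshold,
                notes="misaligned; still misaligned after one realignment retry")
        tree = config.gene_tree or build_gene_tree(realigned, config.gamma_shape)
        summary = distance_summary(tree, accepted, config.sd_multiplier,
                                   config.min_accepted)
        d = candidate_mean_distance(tree, cand, accepted)
        notes.append("realigned once")
        if d <= summary.threshold:
            return CandidateDecision(cand, "1", True, candidate_mean_distance=d,
                                     threshold_used=summary.threshold,
                                     notes="; ".join(notes))
    if is_plausible(tree, cand, accepted, taxonomy, config.plausibility_rank):
        notes.append("over threshold but plausibly placed; flagged")
        return CandidateDecision(cand, "2c", True, flagged=True,
                                 candidate_mean_distance=d,
                                 threshold_used=summary.threshold,
                                 notes="; ".join(notes))
    notes.append("over threshold and implausibly placed; likely paralogue")
    return CandidateDecision(cand, "2b", False, candidate_mean_distance=d,
                             threshold_used=summary.threshold,
                             notes="; ".join(notes))


def _screen_multiple(candidates: set[str], accepted: set[str],
                     taxonomy: TaxonomyMap, config: ScreenConfig, tree: Tree,
                     summary: DistanceSummary,
                     mean_d: Mapping[str, float]) -> list[CandidateDecision]:
    thr = summary.threshold
    cands = sorted(candidates)
    clade = is_candidate_clade(tree, candidates)
    clade_avg = float(np.mean([mean_d[c] for c in cands]))

    def decision(c, rule, acc, note=""):
        return CandidateDecision(c, rule, acc, flagged=False,
                                 candidate_mean_distance=mean_d[c],
                                 threshold_used=thr, notes=note)

    if clade and clade_avg <= thr:
        # in-paralog clade: keep the shortest terminal branch (ties: smallest id)
        keep = min(cands, key=lambda c: (_pendant_length(tree, c), c))
        return [
            decision(c, "3a", c == keep,
                     "shortest terminal branch in candidate clade" if c == keep
                     else f"in-paralog clade-mate of {keep}; not retained")
            for c in cands
        ]
    below = [c for c in cands if mean_d[c] <= thr]
    if not below:
        return [decision(c, "3c", False, "all candidates over threshold")
                for c in cands]
    if not clade and len(below) == 1:
        keep = below[0]
        if is_plausible(tree, keep, accepted, taxonomy, config.plausibility_rank):
            return [
                decision(c, "3b", c == keep,
                         "only candidate within threshold; plausibly placed"
                         if c == keep else "over threshold; not retained")
                for c in cands
            ]
        return [decision(c, "indeterminate", False,
                         "single within-threshold candidate implausibly placed; "
                         "manual review") for c in cands]
    return [decision(c, "indeterminate", False,
                     "configuration outside the decision table; manual review")
            for c in cands]
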