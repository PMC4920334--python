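"""Per-branch relative-rate diagnostics for chronograms.

Pairing a chronogram (branch durations in Myr) with the same topology whose
branch lengths are in substitutions/site yields a per-branch rate
(subs/site/Myr). Two summaries criticise a chronogram's clock behaviour:
the fraction of (by default internal) branches sitting exactly at the
tree-wide median rate — a signature of a rate prior that was never updated —
and a one-sided permutation test for whether those at-median branches
cluster root-ward (older branch midpoints) rather than being spread evenly
over the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .errors import TopologyMismatchError, ValidationError
from .phylo_io import Tree
from .timescale import AGE_ATTR, Chronogram

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BranchRate:
    """One non-root branch: duration, substitution length, their ratio, and
    the branch midpoint age (Ma) used for root-ward clustering."""

    branch_id: str  # label of the child node / clade
    duration: float
    subs_length: float
    is_internal: bool
    midpoint_age: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError(f"branch {self.branch_id}: duration must be > 0")
        if self.subs_length < 0:
            raise ValidationError(f"branch {self.branch_id}: negative length")

    @property
    def rate(self) -> float:
        return self.subs_length / self.duration


def _clade_map(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out[leaves] = node
    return out


def branch_rates(chronogram: Chronogram, subs_tree: Tree) -> list[BranchRate]:
    """Per-branch rates from a chronogram and a substitutions-unit tree of
    identical topology. Branches are matched by the tip set below them; a
    missing bipartition raises :class:`TopologyMismatchError` naming it."""
    if subs_tree.unit != "substitutions_per_site":
        raise ValidationError("subs_tree must be in substitutions/site")
    chrono_map = _clade_map(chronogram.dtree)
    subs_map = _clade_map(subs_tree.dtree)
    if set(chronogram.tree.tip_names) != set(subs_tree.tip_names):
        raise TopologyMismatchError("tip sets differ between the two trees")
    rates = []
    for leaves, node in sorted(chrono_map.items(),
                               key=lambda kv: sorted(kv[0])):
        if leaves not in subs_map:
            raise TopologyMismatchError(
                f"bipartition {{{','.join(sorted(leaves))}}} absent from the "
                "substitution tree"
            )
        duration = node.edge.length
        subs = subs_map[leaves].edge.length or 0.0
        parent_age = getattr(node.parent_node, AGE_ATTR)
        child_age = getattr(node, AGE_ATTR)
        label = (node.taxon.label if node.is_leaf()
                 else "{" + ",".join(sorted(leaves)) + "}")
        rates.append(BranchRate(label, duration, subs,
                                is_internal=not node.is_leaf(),
                                midpoint_age=(parent_age + child_age) / 2.0))
    return rates


def median_rate_fraction(rates: Sequence[BranchRate], rel_tol: float = 1e-6,
                         internal_only: bool = True) -> tuple[float, float]:
    """(median rate, fraction of branches within ``rel_tol`` of it).

    The median is taken over internal branches only by default, matching the
    usual focus on the tree's backbone; a branch counts as at-median when
    ``|rate - median| <= rel_tol * median``.
    """
    selected = [r for r in rates if r.is_internal] if internal_only else list(rates)
    if not selected:
        raise ValidationError("no branches selected")
    values = np.array([r.rate for r in selected])
    med = float(np.median(values))
    frac = float(np.mean(np.abs(values - med) <= rel_tol * med))
    return med, frac


def at_median_mask(rates: Sequence[BranchRate], rel_tol: float = 1e-6,
                   internal_only: bool = True) -> tuple[list[BranchRate], np.ndarray]:
    selected = [r for r in rates if r.is_internal] if internal_only else list(rates)
    med, _ = median_rate_fraction(rates, rel_tol, internal_only)
    mask = np.array([abs(r.rate - med) <= rel_tol * med for r in selected])
    return selected, mask


def rootward_clustering(rates: Sequence[BranchRate], rel_tol: float = 1e-6,
                        n_perm: int = 999, seed: int = 0,
                        internal_only: bool = True) -> tuple[float, float]:
    """One-sided permutation test for root-ward clustering of at-median branches.

    The statistic is mean(midpoint age of at-median branches) − mean(midpoint
    age of the rest); positive values mean the at-median branches sit deeper
    (root-ward) in time. The p-value is the smoothed one-sided permutation
    fraction ``(1 + #{perm >= obs}) / (n_perm + 1)``, reproducible for a
    fixed seed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    selected, mask = at_median_mask(rates, rel_tol, internal_only)
    k = int(mask.sum())
    n = len(selected)
    if k == 0 or k == n:
        raise ValidationError(
            f"clustering test needs both groups non-empty "
            f"(at-median: {k} of {n})"
        )
    ages = np.array([r.midpoint_age for r in selected])
    obs = float(ages[mask].mean() - ages[~mask].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)[:k]
        pmask = np.zeros(n, dtype=bool)
        pmask[perm] = True
        stat = ages[pmask].mean() - ages[~pmask].mean()
        if stat >= obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    logger.info("root-ward clustering: statistic %.4f, p = %.4f "
                "(%d at-median of %d)", obs, p, k, n)
    return obs, float(p)
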