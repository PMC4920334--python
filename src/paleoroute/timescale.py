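"""Fossil-aware minimum-age timescaling of a topology into a chronogram.

Given a rooted topology, tip occurrence ages (0 for extant tips, positive Ma
for fossils) and node calibrations (minimum and optional maximum MRCA ages),
a single post-order pass assigns each internal node the oldest age implied
by its children plus a minimum branch duration, lifted to any calibration
minimum attached to that node. This is deliberately the simple, deterministic
minimum-age scaling; stochastic calibration methods are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .errors import ConstraintConflictError, ValidationError
from .phylo_io import CalibrationSet, Tree

logger = logging.getLogger(__name__)

AGE_ATTR = "age"


class Chronogram:
    """A tree whose branch lengths are durations in Myr and whose nodes carry
    absolute ages in Ma (tips may have positive ages: fossils).

    Node ages are stored on the underlying dendropy nodes (attribute
    ``age``); internal nodes are labelled ``n1, n2, ...`` in preorder for
    reporting.
    """

    def __init__(self, tree: Tree):
        if tree.unit != "Myr":
            raise ValidationError("chronogram branch lengths must be in Myr")
        self.tree = tree
        self._label_internal_nodes()

    def _label_internal_nodes(self):
        i = 0
        for node in self.tree.dtree.preorder_node_iter():
            if node.is_leaf():
                continue
            if not getattr(node, "label", None):
                i += 1
                node.label = f"n{i}"

    @property
    def dtree(self) -> dendropy.Tree:
        return self.tree.dtree

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def ages(self) -> dict[str, float]:
        return {
            self.node_label(n): getattr(n, AGE_ATTR)
            for n in self.dtree.preorder_node_iter()
        }

    def root_age(self) -> float:
        return getattr(self.dtree.seed_node, AGE_ATTR)

    def to_newick(self) -> str:
        return self.tree.to_newick()

    @classmethod
    def from_newick(cls, text: str, tip_ages: Mapping[str, float] | None = None
                    ) -> "Chronogram":
        """Build a chronogram from a Newick string whose branch lengths are
        durations in Myr; node ages are reconstructed from root depth.
        Fossil tip ages may be given to validate the reconstruction."""
        tree = Tree.from_newick(text, unit="Myr")
        depth: dict[dendropy.Node, float] = {}
        maxdepth = 0.0
        for node in tree.dtree.preorder_node_iter():
            parent = node.parent_node
            depth[node] = (depth[parent] + (node.edge.length or 0.0)) \
                if parent is not None else 0.0
            maxdepth = max(maxdepth, depth[node])
        base = maxdepth
        if tip_ages:
            # anchor absolute ages on the oldest-reaching tip
            offs = [
                tip_ages.get(lf.taxon.label, 0.0) + depth[lf]
                for lf in tree.dtree.leaf_node_iter()
            ]
            base = max(offs)
        for node in tree.dtree.preorder_node_iter():
            setattr(node, AGE_ATTR, base - depth[node])
        return cls(tree)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def assign_node_ages(topology: Tree, tip_ages: Mapping[str, float],
                     calibrations: CalibrationSet | None = None,
                     min_branch: float = 1.0) -> Chronogram:
    """Timescale ``topology`` by the minimum-age rule.

    Post-order: each internal node's age is the maximum of (oldest child age
    + ``min_branch``) and any calibration minimum whose MRCA resolves to the
    node. Calibration maxima are hard checks: a constructed age above a
    maximum raises :class:`ConstraintConflictError` (silent age compression
    would corrupt downstream rates). Branch lengths of the result are
    durations in Myr.
    """
    calibrations = calibrations or CalibrationSet([])
    tree = topology.clone()
    tips = set(tree.tip_names)
    missing = tips - set(tip_ages)
    if missing:
        raise ValidationError(f"tips without ages: {sorted(missing)}")
    calibrations.check_against(tree)

    cal_min: dict[dendropy.Node, float] = {}
    cal_max: dict[dendropy.Node, float] = {}
    for cal in calibrations:
        mrca = tree.dtree.mrca(taxon_labels=list(cal.clade))
        if mrca is None or mrca.is_leaf():
            raise ValidationError(
                f"calibration clade {sorted(cal.clade)} does not resolve to "
                "an internal node"
            )
        cal_min[mrca] = max(cal_min.get(mrca, 0.0), cal.min_age)
        if cal.max_age is not None:
            cal_max[mrca] = min(cal_max.get(mrca, float("inf")), cal.max_age)

    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            age = float(tip_ages[node.taxon.label])
            if age < 0:
                raise ValidationError(f"negative tip age for {node.taxon.label!r}")
        else:
            age = max(getattr(c, AGE_ATTR) for c in node.child_nodes()) + min_branch
            if node in cal_min:
                age = max(age, cal_min[node])
        if node in cal_max and age > cal_max[node]:
            raise ConstraintConflictError(
                f"node above {sorted(l.taxon.label for l in node.leaf_iter())} "
                f"requires age {age:g} Ma > calibration maximum {cal_max[node]:g}"
            )
        setattr(node, AGE_ATTR, age)

    # pre-order monotonicity enforcement and duration assignment
    for node in tree.dtree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            node.edge.length = None
            continue
        dur = getattr(parent, AGE_ATTR) - getattr(node, AGE_ATTR)
        if dur < min_branch - 1e-9:
            raise ConstraintConflictError(
                f"branch above {_describe(node)} has duration {dur:g} "
                f"< min_branch {min_branch:g}"
            )
        node.edge.length = dur

    tree.unit = "Myr"
    chrono = Chronogram(tree)
    logger.info("timescaled %d tips; root age %.3f Ma", len(tips),
                chrono.root_age())
    return chrono


def _describe(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "{" + ",".join(sorted(l.taxon.label for l in node.leaf_iter())) + "}"


def validate_chronogram(chronogram: Chronogram, min_branch: float = 0.0,
                        extant_tips: set[str] | None = None) -> ValidationReport:
    """Check every chronogram invariant; violations are reported, not raised.

    ``extant_tips``, when given, must all sit at age 0.
    """
    report = ValidationReport()
    dtree = chronogram.dtree
    root = dtree.seed_node
    root_age = getattr(root, AGE_ATTR, None)
    if root_age is None:
        report.violations.append("root has no age")
        return report
    for node in dtree.preorder_node_iter():
        age = getattr(node, AGE_ATTR, None)
        label = chronogram.node_label(node)
        if age is None:
            report.violations.append(f"node {label} has no age")
            continue
        if age < 0:
            report.violations.append(f"node {label} has negative age {age:g}")
        if age > root_age + 1e-9:
            report.violations.append(f"node {label} older than the root")
        parent = node.parent_node
        if parent is not None:
            page = getattr(parent, AGE_ATTR, None)
            if page is not None and page < age + min_branch - 1e-9:
                report.violations.append(
                    f"parent of {label} ({page:g} Ma) younger than child + "
                    f"min_branch ({age:g} + {min_branch:g})"
                )
            if node.edge.length is not None and page is not None and \
                    abs(node.edge.length - (page - age)) > 1e-6:
                report.violations.append(
                    f"branch length above {label} inconsistent with node ages"
                )
    if extant_tips:
        for name in sorted(extant_tips):
            try:
                tip = chronogram.tree.find_tip(name)
            except KeyError:
                report.violations.append(f"extant tip {name!r} not in tree")
                continue
            if abs(getattr(tip, AGE_ATTR, 0.0)) > 1e-9:
                report.violations.append(
                    f"extant tip {name!r} has nonzero age "
                    f"{getattr(tip, AGE_ATTR):g}"
                )
    return report
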