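"""Readers, writers and domain types for every external format the pipeline touches.

Sequences and alignments are FASTA (via Biopython), trees are Newick (via
DendroPy), similarity hits and habitat/calibration tables are delimited text
(via pandas). Every reader validates the invariants of the type it returns
and raises a located error on violation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    DuplicateIdError,
    FormatError,
    NewickParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_ALPHABET = frozenset(AMINO_ACIDS + "-X")

#: Habitat states used throughout the ancestral-environment analysis.
DEFAULT_HABITAT_STATES = ("marine", "brackish", "freshwater")


# ---------------------------------------------------------------------------
# sequence types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One (possibly gapped) amino-acid sequence.

    ``id`` must be whitespace-free and unique within a file; ``taxon`` is a
    free-text label defaulting to the id. Residues are restricted to the 20
    amino-acid letters plus gap ``-`` and unknown ``X``.
    """

    id: str
    residues: str
    taxon: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"sequence id {self.id!r} empty or contains whitespace")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues.upper()) - RESIDUE_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )
        if not self.taxon:
            object.__setattr__(self, "taxon", self.id)
        object.__setattr__(self, "residues", self.residues.upper())

    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


class Msa:
    """An ordered multiple sequence alignment with uniform column count."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValidationError("alignment must contain at least one record")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise ValidationError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DuplicateIdError(f"duplicate sequence id {dup!r} in alignment")
        self.records = records
        self.n_columns = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def take_columns(self, columns: Sequence[int]) -> "Msa":
        return Msa(
            [
                SequenceRecord(r.id, "".join(r.residues[j] for j in columns), r.taxon)
                for r in self.records
            ]
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The first whitespace-delimited token of the header is the id; a second
    token, when present, is used as the taxon label.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        parts = rec.description.split()
        taxon = parts[1] if len(parts) > 1 else rec.id
        records.append(SequenceRecord(rec.id, str(rec.seq), taxon))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    logger.info("read %d sequences from %s", len(records), path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id,
                      description=r.taxon if r.taxon != r.id else "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file as an :class:`Msa`."""
    return Msa(read_fasta(path))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class Tree:
    """A rooted tree with named tips, non-negative branch lengths and a
    length unit tag (``substitutions_per_site``, ``Myr`` or ``unitless``).

    Thin wrapper around a :class:`dendropy.Tree`; the underlying object is
    exposed as ``.dtree`` for traversal.
    """

    UNITS = ("substitutions_per_site", "Myr", "unitless")

    def __init__(self, dtree: dendropy.Tree, unit: str = "unitless"):
        if unit not in self.UNITS:
            raise ValidationError(f"unknown branch-length unit {unit!r}")
        self.dtree = dtree
        self.unit = unit
        self._validate()

    def _validate(self):
        names = [lf.taxon.label for lf in self.dtree.leaf_node_iter() if lf.taxon]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise DuplicateIdError(f"duplicate tip name {dup!r}")
        for edge in self.dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(
                    f"negative branch length {edge.length} above node "
                    f"{getattr(edge.head_node.taxon, 'label', None)!r}"
                )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, unit: str = "unitless") -> "Tree":
        return parse_newick(text, unit=unit)

    @classmethod
    def from_file(cls, path: str | Path, unit: str = "unitless") -> "Tree":
        return parse_newick(Path(path).read_text(), unit=unit)

    # -- queries ------------------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def find_tip(self, name: str) -> dendropy.Node:
        for lf in self.dtree.leaf_node_iter():
            if lf.taxon and lf.taxon.label == name:
                return lf
        raise KeyError(f"tip {name!r} not in tree")

    def patristic_matrix(self) -> tuple[list[str], np.ndarray]:
        """Tip labels (sorted) and the symmetric matrix of tip-to-tip path
        lengths. Raises on any missing branch length."""
        for edge in self.dtree.preorder_edge_iter():
            if edge.head_node is not self.dtree.seed_node and edge.length is None:
                raise ValidationError("missing branch length on a non-root edge")
        labels = sorted(self.tip_names)
        pdm = self.dtree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in self.dtree.taxon_namespace}
        n = len(labels)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(tax[labels[i]], tax[labels[j]])
                mat[i, j] = mat[j, i] = d
        return labels, mat

    def to_newick(self) -> str:
        s = self.dtree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        )
        return s.strip()

    def clone(self) -> "Tree":
        return Tree(self.dtree.clone(depth=1), unit=self.unit)


def _check_balanced(text: str) -> None:
    depth = 0
    for i, c in enumerate(text):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at offset {i}", offset=i)
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open", offset=len(text) - 1
        )


def parse_newick(text: str, unit: str = "unitless") -> Tree:
    """Parse a single semicolon-terminated Newick description.

    Quoted labels and internal node names are supported; square-bracket
    comments are ignored. Unbalanced parentheses and negative branch lengths
    raise :class:`NewickParseError` with a character offset.
    """
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"Newick parse failed: {exc}") from exc
    dtree.is_rooted = True
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise NewickParseError(
                f"negative branch length {edge.length}",
                offset=text.find(str(edge.length)),
            )
    return Tree(dtree, unit=unit)


# ---------------------------------------------------------------------------
# similarity hit tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One query/subject similarity hit with an E-value."""

    query: str
    subject: str
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError(
                f"negative E-value {self.evalue} for {self.query}/{self.subject}"
            )


def read_hit_table(path: str | Path, evalue_col: int | None = None) -> list[HitRecord]:
    """Read a tab-separated similarity hit table.

    Two dialects are supported and are NOT autodetected beyond column count:
    the minimal 3-column ``query  subject  evalue`` layout (E-value column 3)
    and the standard 12-column tabular search output (E-value column 11).
    ``evalue_col`` (1-based) overrides either default. Rows with a
    non-numeric E-value raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ncol = df.shape[1]
    if ncol < 3:
        raise FormatError(f"{path}: expected >= 3 tab-separated columns, found {ncol}")
    if evalue_col is None:
        if ncol == 3:
            evalue_col = 3
        elif ncol == 12:
            evalue_col = 11
        else:
            raise FormatError(
                f"{path}: {ncol} columns is neither the 3- nor the 12-column "
                "dialect; pass evalue_col explicitly"
            )
    if not 3 <= evalue_col <= ncol:
        raise FormatError(f"evalue_col {evalue_col} out of range for {ncol} columns")
    ev = pd.to_numeric(df.iloc[:, evalue_col - 1], errors="coerce")
    if ev.isna().any():
        line = int(ev.index[ev.isna()][0]) + 1
        raise FormatError(
            f"{path}: non-numeric E-value "
            f"{df.iloc[line - 1, evalue_col - 1]!r} at line {line}"
        )
    hits = [
        HitRecord(q, s, float(e))
        for q, s, e in zip(df.iloc[:, 0], df.iloc[:, 1], ev)
    ]
    logger.info("read %d hits from %s", len(hits), path)
    return hits


# ---------------------------------------------------------------------------
# habitat matrices
# ---------------------------------------------------------------------------

@dataclass
class HabitatMatrix:
    """Tip habitat states (plus optional fossil tip ages in Ma).

    ``states`` maps taxon label -> state; ``tip_age`` maps taxon -> age in
    Ma (0 for extant tips). The state alphabet defaults to the three
    aquatic-habitat states but is user-configurable so the Mk machinery
    generalizes to k states.
    """

    states: dict[str, str]
    tip_age: dict[str, float] = field(default_factory=dict)
    alphabet: tuple[str, ...] = DEFAULT_HABITAT_STATES

    def __post_init__(self):
        for taxon, state in self.states.items():
            if state == "?":  # ambiguous/missing observation
                continue
            if state not in self.alphabet:
                raise ValidationError(
                    f"unknown state {state!r} for taxon {taxon!r}; "
                    f"alphabet is {list(self.alphabet)}"
                )
        for taxon in self.states:
            self.tip_age.setdefault(taxon, 0.0)
            if self.tip_age[taxon] < 0:
                raise ValidationError(f"negative tip age for {taxon!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.states)

    def __getitem__(self, taxon: str) -> str:
        return self.states[taxon]

    def __len__(self) -> int:
        return len(self.states)


def read_habitat_matrix(
    path: str | Path, alphabet: Sequence[str] = DEFAULT_HABITAT_STATES
) -> HabitatMatrix:
    """Read a delimited table with columns taxon, state and optional age_Ma.

    A header row is recognized when the first field is literally ``taxon``.
    Missing ages default to 0 (extant). Unknown state tokens raise
    :class:`ValidationError` naming the taxon and the token.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#",
                     dtype=str, skip_blank_lines=True)
    if str(df.iloc[0, 0]).strip().lower() == "taxon":
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least taxon and state columns")
    states: dict[str, str] = {}
    ages: dict[str, float] = {}
    for _, row in df.iterrows():
        taxon = str(row.iloc[0]).strip()
        state = row.iloc[1]
        if state is None or (isinstance(state, float) and np.isnan(state)) \
                or str(state).strip() == "":
            raise FormatError(f"{path}: empty state for taxon {taxon!r}")
        state = str(state).strip()
        if state not in alphabet:
            raise ValidationError(
                f"{path}: unknown state {state!r} for taxon {taxon!r}"
            )
        if taxon in states:
            raise DuplicateIdError(f"{path}: duplicate taxon {taxon!r}")
        states[taxon] = state
        if df.shape[1] > 2 and not pd.isna(row.iloc[2]) and str(row.iloc[2]).strip():
            ages[taxon] = float(row.iloc[2])
    logger.info("read habitat states for %d taxa from %s", len(states), path)
    return HabitatMatrix(states, ages, tuple(alphabet))


def write_habitat_matrix(matrix: HabitatMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tstate\tage_Ma\n")
        for taxon, state in matrix.states.items():
            fh.write(f"{taxon}\t{state}\t{matrix.tip_age[taxon]:g}\n")


# ---------------------------------------------------------------------------
# calibrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """A minimum (and optional maximum) age constraint on the MRCA of a clade."""

    clade: frozenset[str]
    min_age: float
    max_age: float | None = None

    def __post_init__(self):
        if len(self.clade) < 2:
            raise ValidationError("calibration clade needs >= 2 tip labels")
        if self.max_age is not None and self.min_age > self.max_age:
            raise ValidationError(
                f"calibration min_age {self.min_age} > max_age {self.max_age}"
            )


@dataclass
class CalibrationSet:
    entries: list[Calibration]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def check_against(self, tree: Tree) -> None:
        tips = set(tree.tip_names)
        for cal in self.entries:
            missing = cal.clade - tips
            if missing:
                raise ValidationError(
                    f"calibration clade tips not in tree: {sorted(missing)}"
                )


def read_calibration_table(path: str | Path) -> CalibrationSet:
    """Read a tab-separated calibration table.

    Columns: comma-separated tip labels defining the MRCA, min_age, and an
    optional max_age. Lines beginning with ``#`` are comments.
    """
    path = Path(path)
    entries: list[Calibration] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("clade\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected clade<TAB>min_age")
        clade = frozenset(t.strip() for t in parts[0].split(",") if t.strip())
        min_age = float(parts[1])
        max_age = float(parts[2]) if len(parts) > 2 and parts[2].strip() else None
        entries.append(Calibration(clade, min_age, max_age))
    logger.info("read %d calibrations from %s", len(entries), path)
    return CalibrationSet(entries)
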