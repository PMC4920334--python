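"""Block-based alignment trimming and supermatrix concatenation.

The trimmer is a documented, simplified block rule driven by the four
classic settings of conserved-block trimming (minimum conserved fraction,
flank fraction, minimum block length, maximum gap fraction): a column is
first classified, then the maximal runs of acceptable columns that are long
enough and flanked by highly conserved columns are kept. The concatenator
joins per-gene alignments over the union of taxa, padding absentees with
gaps and emitting a 1-based inclusive partition table.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError
from .phylo_io import Msa, SequenceRecord

logger = logging.getLogger(__name__)

GAP_EXCLUDED = "gap_excluded"
NONCONSERVED = "nonconserved"
CONSERVED = "conserved"
HIGHLY_CONSERVED = "highly_conserved"


@dataclass(frozen=True)
class TrimParams:
    """Settings of the block trimmer.

    ``conserved_fraction`` — minimum modal-residue frequency for a conserved
    column (default 0.5); ``flank_fraction`` — minimum for a highly conserved
    (flank-quality) column (default 0.75); ``min_block`` — minimum kept block
    length (default 5); ``max_gap_fraction`` — columns with a larger gap
    fraction are excluded outright (default 0.5, i.e. gaps allowed in up to
    half the rows). Modal frequency is computed over ALL rows, so gaps count
    against conservation.
    """

    conserved_fraction: float = 0.5
    flank_fraction: float = 0.75
    min_block: int = 5
    max_gap_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.conserved_fraction <= 1:
            raise ValidationError("conserved_fraction must be in (0, 1]")
        if not 0 < self.flank_fraction <= 1:
            raise ValidationError("flank_fraction must be in (0, 1]")
        if self.flank_fraction < self.conserved_fraction:
            raise ValidationError("flank_fraction must be >= conserved_fraction")
        if self.min_block < 1:
            raise ValidationError("min_block must be positive")
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValidationError("max_gap_fraction must be in [0, 1]")


def classify_columns(msa: Msa, params: TrimParams | None = None) -> list[str]:
    """Per-column conservation label.

    A column is ``gap_excluded`` when its gap fraction exceeds
    ``max_gap_fraction``; otherwise it is ``highly_conserved``/``conserved``/
    ``nonconserved`` by the modal non-gap residue's frequency over all rows.
    """
    params = params or TrimParams()
    n_rows = len(msa)
    labels = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        gap_frac = col.count("-") / n_rows
        if gap_frac > params.max_gap_fraction:
            labels.append(GAP_EXCLUDED)
            continue
        counts = Counter(c for c in col if c != "-")
        modal_frac = (max(counts.values()) / n_rows) if counts else 0.0
        if modal_frac >= params.flank_fraction:
            labels.append(HIGHLY_CONSERVED)
        elif modal_frac >= params.conserved_fraction:
            labels.append(CONSERVED)
        else:
            labels.append(NONCONSERVED)
    return labels


def trim(msa: Msa, params: TrimParams | None = None) -> tuple[Msa | None, list[int]]:
    """Keep the maximal runs of conserved-or-better columns that are at least
    ``min_block`` long and begin and end on a highly conserved column.

    Returns the trimmed alignment (``None`` when no block survives) and the
    kept column indices, 1-based and strictly increasing.
    """
    params = params or TrimParams()
    labels = classify_columns(msa, params)
    kept: list[int] = []
    run: list[int] = []

    def flush(run):
        # shrink the run to its outermost highly conserved columns
        while run and labels[run[0]] != HIGHLY_CONSERVED:
            run.pop(0)
        while run and labels[run[-1]] != HIGHLY_CONSERVED:
            run.pop()
        if len(run) >= params.min_block:
            kept.extend(run)

    for j, lab in enumerate(labels):
        if lab in (CONSERVED, HIGHLY_CONSERVED):
            run.append(j)
        else:
            flush(run)
            run = []
    flush(run)

    if not kept:
        logger.info("trimming removed every column (%d in)", msa.n_columns)
        return None, []
    trimmed = msa.take_columns(kept)
    logger.info("trimming kept %d/%d columns", len(kept), msa.n_columns)
    return trimmed, [j + 1 for j in kept]


@dataclass
class Supermatrix:
    """Concatenated per-gene alignments over the union of taxa.

    ``partitions`` holds (gene, start, end) in 1-based inclusive columns and
    tiles the matrix; ``occupancy`` is each taxon's fraction of non-gap
    columns.
    """

    alignment: Msa
    partitions: list[tuple[str, int, int]]
    occupancy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        expect = 1
        for gene, start, end in self.partitions:
            if start != expect or end < start:
                raise ValidationError(f"partition {gene} does not tile the matrix")
            expect = end + 1
        if expect != self.alignment.n_columns + 1:
            raise ValidationError("partitions do not cover all columns")


def concatenate(gene_alignments: Mapping[str, Msa]) -> Supermatrix:
    """Concatenate per-gene alignments (keyed by taxon within each gene).

    Genes are ordered lexicographically by name for determinism; taxa absent
    from a gene are padded with gaps across its partition.
    """
    if not gene_alignments:
        raise ValidationError("no gene alignments to concatenate")
    genes = sorted(gene_alignments)
    for g in genes:
        if gene_alignments[g].n_columns == 0:
            raise ValidationError(f"gene {g!r} has zero columns")
    taxa = sorted({r.taxon for g in genes for r in gene_alignments[g]})
    parts: list[tuple[str, int, int]] = []
    rows = {t: [] for t in taxa}
    col = 1
    for g in genes:
        msa = gene_alignments[g]
        width = msa.n_columns
        by_taxon = {}
        for r in msa:
            if r.taxon in by_taxon:
                raise ValidationError(f"gene {g!r}: duplicate taxon {r.taxon!r}")
            by_taxon[r.taxon] = r.residues
        for t in taxa:
            rows[t].append(by_taxon.get(t, "-" * width))
        parts.append((g, col, col + width - 1))
        col += width
    records = [SequenceRecord(t, "".join(rows[t]), t) for t in taxa]
    aln = Msa(records)
    occupancy = {
        r.taxon: 1 - r.residues.count("-") / aln.n_columns for r in records
    }
    logger.info("supermatrix: %d taxa x %d columns, %d partitions",
                len(taxa), aln.n_columns, len(parts))
    return Supermatrix(aln, parts, occupancy)
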