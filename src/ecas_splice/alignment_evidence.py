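"""Reduce spliced alignments to the evidence tables the pipeline consumes.

Three tables are produced per species/library: splice-junction support
(one row per distinct gap), per-intron coverage (breadth and read count
against the annotated introns) and per-gene exonic read counts. Only
primary alignments contribute; a read is counted as uniquely aligned when
it is primary and carries no NH tag > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pysam

from ecas_splice.annotation_model import Annotation, IntronInterval


class EvidenceError(ValueError):
    """Bad alignment or evidence-table input."""


@dataclass
class JunctionEvidence:
    """One observed splice junction (the gap an N CIGAR op skips).

    ``intron_start``/``intron_end`` are the 1-based inclusive bounds of the
    skipped reference bases. ``min_overhang`` is the smallest aligned block
    flanking the gap on either side over all supporting reads.
    """

    contig_id: str
    intron_start: int
    intron_end: int
    support_reads: int
    min_overhang: int
    distinct_positions: int
    unique_support: int

    def __post_init__(self) -> None:
        if not (self.support_reads >= self.distinct_positions >= 1):
            raise EvidenceError(
                f"junction {self.contig_id}:{self.intron_start}-{self.intron_end}: "
                f"support {self.support_reads} < distinct positions {self.distinct_positions}"
            )
        if self.min_overhang < 1:
            raise EvidenceError("min_overhang must be >= 1")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig_id, self.intron_start, self.intron_end)


@dataclass
class IntronCoverage:
    """Read coverage of one annotated intron.

    ``covered_bases`` is breadth: the number of intron positions touched by
    at least one contiguously aligned block. ``intron_reads`` counts reads
    with >= 1 aligned base inside the intron.
    """

    gene_id: str
    intron_index: int  # 0-based, transcription order
    intron: IntronInterval
    covered_bases: int
    intron_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.covered_bases <= self.intron.length):
            raise EvidenceError(
                f"{self.gene_id} intron {self.intron_index}: covered_bases "
                f"{self.covered_bases} outside [0, {self.intron.length}]"
            )


@dataclass
class LibraryStats:
    species_id: str
    total_mapped_reads: int
    uniquely_mapped_reads: int

    def __post_init__(self) -> None:
        if self.uniquely_mapped_reads > self.total_mapped_reads:
            raise EvidenceError(
                f"{self.species_id}: uniquely mapped ({self.uniquely_mapped_reads}) "
                f"exceeds total mapped ({self.total_mapped_reads})"
            )


@dataclass
class EvidenceTables:
    """Bundle of the three evidence tables for one library."""

    junctions: list[JunctionEvidence]
    intron_coverage: list[IntronCoverage]
    exon_counts: dict[str, int]  # gene_id -> uniquely mapped exonic reads
    library: LibraryStats


def _is_unique(read: pysam.AlignedSegment) -> bool:
    if read.is_secondary or read.is_supplementary:
        return False
    try:
        return read.get_tag("NH") <= 1
    except KeyError:
        return True


def _gaps_with_flanks(read: pysam.AlignedSegment, min_gap: int):
    """Yield (gap_start, gap_end, left_flank, right_flank) per N op, 1-based."""
    pos = read.reference_start  # 0-based
    # reference-consuming block lengths between gaps
    segments: list[int] = [0]
    gaps: list[tuple[int, int]] = []
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            segments[-1] += length
            pos += length
        elif op == 2:  # D: consumes reference but stays contiguous
            segments[-1] += length
            pos += length
        elif op == 3:  # N: the splice gap
            gaps.append((pos + 1, pos + length))
            pos += length
            segments.append(0)
        # I, S, H, P: no reference advance
    for i, (gstart, gend) in enumerate(gaps):
        if gend - gstart + 1 >= min_gap:
            yield gstart, gend, segments[i], segments[i + 1]


def extract_evidence(
    alignment_path,
    annotation: Annotation,
    species_id: str = "sample",
    min_gap: int = 20,
) -> EvidenceTables:
    """Scan a SAM/BAM file and build the three evidence tables.

    Every alignment gap of at least ``min_gap`` reference bases becomes
    junction evidence; multi-gap reads contribute to each of their gaps.
    """
    junc: dict[tuple[str, int, int], dict] = {}
    cov_bases: dict[tuple[str, int], set[int]] = {}
    cov_reads: dict[tuple[str, int], int] = {}
    exon_counts: dict[str, int] = {g: 0 for g in annotation.genes}
    total_mapped = 0
    unique_mapped = 0

    # introns derived once per gene; reads only consult overlapping genes
    gene_introns = {g.gene_id: g.introns for g in annotation.genes.values()}

    n_records = 0
    mode = "rb" if str(alignment_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as sam:
        for read in sam:
            n_records += 1
            if read.is_unmapped:
                continue
            if read.is_secondary or read.is_supplementary:
                continue
            if read.cigartuples is None:
                raise EvidenceError(f"read {read.query_name}: missing CIGAR")
            total_mapped += 1
            unique = _is_unique(read)
            if unique:
                unique_mapped += 1
            contig = read.reference_name
            start_1b = read.reference_start + 1

            for gstart, gend, left, right in _gaps_with_flanks(read, min_gap):
                key = (contig, gstart, gend)
                rec = junc.setdefault(
                    key,
                    {"support": 0, "overhang": None, "positions": set(), "unique": 0},
                )
                rec["support"] += 1
                flank = min(left, right)
                rec["overhang"] = flank if rec["overhang"] is None else min(rec["overhang"], flank)
                rec["positions"].add(start_1b)
                if unique:
                    rec["unique"] += 1

            blocks = [(s + 1, e) for s, e in read.get_blocks()]  # 1-based inclusive
            if not blocks:
                continue
            span_lo, span_hi = blocks[0][0], blocks[-1][1]
            for gene in annotation.genes_overlapping(contig, span_lo, span_hi):
                # intron coverage (breadth + read count)
                for idx, intr in enumerate(gene_introns[gene.gene_id]):
                    touched = False
                    for bstart, bend in blocks:
                        lo, hi = max(bstart, intr.start), min(bend, intr.end)
                        if lo <= hi:
                            touched = True
                            cov_bases.setdefault((gene.gene_id, idx), set()).update(
                                range(lo, hi + 1)
                            )
                    if touched:
                        key = (gene.gene_id, idx)
                        cov_reads[key] = cov_reads.get(key, 0) + 1
                # exonic read counts (unique reads only; one count per gene)
                if unique and any(
                    max(bstart, exon.start) <= min(bend, exon.end)
                    for bstart, bend in blocks
                    for exon in gene.exons
                ):
                    exon_counts[gene.gene_id] += 1

    if total_mapped == 0 and n_records > 0:
        warnings.warn(f"{alignment_path}: no mapped reads", stacklevel=2)

    junctions = [
        JunctionEvidence(
            contig_id=contig,
            intron_start=gstart,
            intron_end=gend,
            support_reads=rec["support"],
            min_overhang=rec["overhang"],
            distinct_positions=len(rec["positions"]),
            unique_support=rec["unique"],
        )
        for (contig, gstart, gend), rec in sorted(junc.items())
    ]

    coverage = []
    for gene_id in sorted(annotation.genes):
        for idx, intr in enumerate(gene_introns[gene_id]):
            coverage.append(
                IntronCoverage(
                    gene_id=gene_id,
                    intron_index=idx,
                    intron=intr,
                    covered_bases=len(cov_bases.get((gene_id, idx), ())),
                    intron_reads=cov_reads.get((gene_id, idx), 0),
                )
            )

    library = LibraryStats(
        species_id=species_id,
        total_mapped_reads=total_mapped,
        uniquely_mapped_reads=unique_mapped,
    )
    return EvidenceTables(junctions, coverage, exon_counts, library)


# ---------------------------------------------------------------------------
# TSV round-trip

JUNCTION_COLUMNS = [
    "contig",
    "intron_start",
    "intron_end",
    "support",
    "min_overhang",
    "distinct_positions",
    "unique_support",
]
INTRON_COLUMNS = ["gene_id", "intron_index", "covered_bases", "intron_reads"]
LIBRARY_COLUMNS = ["species_id", "total_mapped", "uniquely_mapped"]
EXON_COLUMNS = ["gene_id", "exonic_reads"]


def write_evidence_tables(tables: EvidenceTables, junction_tsv, intron_tsv, stats_tsv, exon_tsv=None):
    pd.DataFrame(
        [
            (j.contig_id, j.intron_start, j.intron_end, j.support_reads,
             j.min_overhang, j.distinct_positions, j.unique_support)
            for j in tables.junctions
        ],
        columns=JUNCTION_COLUMNS,
    ).to_csv(junction_tsv, sep="\t", index=False)
    pd.DataFrame(
        [
            (c.gene_id, c.intron_index, c.covered_bases, c.intron_reads)
            for c in tables.intron_coverage
        ],
        columns=INTRON_COLUMNS,
    ).to_csv(intron_tsv, sep="\t", index=False)
    pd.DataFrame(
        [(tables.library.species_id, tables.library.total_mapped_reads,
          tables.library.uniquely_mapped_reads)],
        columns=LIBRARY_COLUMNS,
    ).to_csv(stats_tsv, sep="\t", index=False)
    if exon_tsv is not None:
        pd.DataFrame(
            sorted(tables.exon_counts.items()), columns=EXON_COLUMNS
        ).to_csv(exon_tsv, sep="\t", index=False)


def load_evidence_tables(
    junction_tsv, intron_tsv, stats_tsv, annotation: Annotation, exon_tsv=None
) -> EvidenceTables:
    """Load evidence from TSVs; behaves identically to :func:`extract_evidence`."""

    def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise EvidenceError(f"{name}: missing column(s) {missing}")

    jdf = pd.read_csv(junction_tsv, sep="\t", comment="#")
    _require(jdf, JUNCTION_COLUMNS, "junction table")
    junctions = [
        JunctionEvidence(
            str(r.contig), int(r.intron_start), int(r.intron_end), int(r.support),
            int(r.min_overhang), int(r.distinct_positions), int(r.unique_support),
        )
        for r in jdf.itertuples()
    ]

    idf = pd.read_csv(intron_tsv, sep="\t", comment="#")
    _require(idf, INTRON_COLUMNS, "intron coverage table")
    coverage = []
    for r in idf.itertuples():
        gene = annotation.genes.get(str(r.gene_id))
        if gene is None:
            raise EvidenceError(f"intron coverage: unknown gene {r.gene_id}")
        introns = gene.introns
        idx = int(r.intron_index)
        if not (0 <= idx < len(introns)):
            raise EvidenceError(f"intron coverage: {r.gene_id} has no intron {idx}")
        coverage.append(
            IntronCoverage(str(r.gene_id), idx, introns[idx], int(r.covered_bases), int(r.intron_reads))
        )

    sdf = pd.read_csv(stats_tsv, sep="\t", comment="#")
    _require(sdf, LIBRARY_COLUMNS, "library stats table")
    row = sdf.iloc[0]
    library = LibraryStats(str(row.species_id), int(row.total_mapped), int(row.uniquely_mapped))

    exon_counts = {g: 0 for g in annotation.genes}
    if exon_tsv is not None:
        edf = pd.read_csv(exon_tsv, sep="\t", comment="#")
        _require(edf, EXON_COLUMNS, "exon count table")
        for r in edf.itertuples():
            exon_counts[str(r.gene_id)] = int(r.exonic_reads)

    return EvidenceTables(junctions, coverage, exon_counts, library)
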