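"""Call the five alternative-splicing event types for one species.

Event types and length rules:

* **IR** — an annotated intron with enough intron-mapped reads (the same
  per-ten-million scaling used for junctions) and breadth >= 0.5 of its
  length. Event length = retained intron length.
* **ES** — a passed junction whose ends coincide with the boundaries of
  two non-adjacent annotated exons; the exons in between are skipped.
  Event length = total skipped exon length. A multi-exon skip is one event.
* **AltD / AltA / AltP** — a passed junction that matches no annotated
  intron exactly, compared against the annotated intron with maximal
  reciprocal overlap. Donor shifted → AltD, acceptor shifted → AltA, both
  → AltP (standard convention; ``swap_alt_labels`` transposes AltD/AltA).
  Length = |shift| at the varying end, or the sum of both for AltP.

A junction exactly matching an annotated intron is constitutive and
generates no event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ecas_splice.alignment_evidence import (
    EvidenceTables,
    IntronCoverage,
    JunctionEvidence,
    LibraryStats,
)
from ecas_splice.annotation_model import Annotation, GeneModel, classify_interval
from ecas_splice.junction_filter import FilterPolicy, filter_junctions, support_threshold

logger = logging.getLogger(__name__)

ES = "ES"
IR = "IR"
ALTD = "AltD"
ALTA = "AltA"
ALTP = "AltP"
EVENT_TYPES = (ES, IR, ALTD, ALTA, ALTP)


@dataclass(frozen=True)
class ASEvent:
    """One called alternative-splicing event."""

    species_id: str
    gene_id: str
    event_type: str
    intervals: tuple[tuple[int, int], ...]  # retained intron / skipped exon(s) / novel junction
    event_length: int
    region: str
    ref_junction: tuple[int, int] | None = None  # annotated intron an Alt event deviates from
    contig_id: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")
        if self.event_length < 1:
            raise ValueError("event_length must be >= 1")
        if self.event_type in (ALTD, ALTA, ALTP) and self.ref_junction is None:
            raise ValueError(f"{self.event_type} event requires a ref_junction")

    @property
    def signature(self) -> tuple:
        """Identity of the event on the shared reference (species-agnostic)."""
        return (self.gene_id, self.event_type, self.intervals, self.ref_junction)


@dataclass
class CallerConfig:
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    min_ir_breadth: float = 0.5
    ir_breadth_mode: str = "breadth"  # or "depth": mean per-base depth proxy
    swap_alt_labels: bool = False  # transpose AltD/AltA naming


def _intron_map(gene: GeneModel) -> dict[tuple[int, int], int]:
    return {(i.start, i.end): k for k, i in enumerate(gene.introns)}


def call_ir(
    intron_coverage: list[IntronCoverage],
    library: LibraryStats,
    annotation: Annotation,
    config: CallerConfig | None = None,
    species_id: str = "sample",
) -> list[ASEvent]:
    """Intron-retention calls from per-intron coverage."""
    config = config or CallerConfig()
    threshold = support_threshold(config.policy, library)
    events = []
    for cov in intron_coverage:
        gene = annotation.genes.get(cov.gene_id)
        if gene is None:
            raise ValueError(f"intron coverage references unknown gene {cov.gene_id}")
        if cov.intron_reads < threshold:
            continue
        if cov.covered_bases / cov.intron.length < config.min_ir_breadth:
            continue
        intr = cov.intron
        events.append(
            ASEvent(
                species_id=species_id,
                gene_id=cov.gene_id,
                event_type=IR,
                intervals=((intr.start, intr.end),),
                event_length=intr.length,
                region=classify_interval(gene, intr.start, intr.end),
                contig_id=gene.contig_id,
            )
        )
    return events


def _find_containing_gene(
    annotation: Annotation, contig: str, left: int, right: int
) -> GeneModel | None:
    for gene in annotation.genes_overlapping(contig, left, right):
        if gene.contains(left, right):
            return gene
    return None


def call_es(
    passed: list[JunctionEvidence],
    annotation: Annotation,
    species_id: str = "sample",
) -> list[ASEvent]:
    """Exon-skipping calls: junctions joining non-adjacent annotated exons."""
    events = []
    for j in passed:
        gene = _find_containing_gene(annotation, j.contig_id, j.intron_start - 1, j.intron_end + 1)
        if gene is None:
            continue
        exons = gene.exons  # genomic order
        left_idx = next(
            (i for i, e in enumerate(exons) if e.end == j.intron_start - 1), None
        )
        right_idx = next(
            (i for i, e in enumerate(exons) if e.start == j.intron_end + 1), None
        )
        if left_idx is None or right_idx is None:
            continue
        if right_idx < left_idx + 2:
            continue  # adjacent exons: constitutive junction, no skip
        skipped = exons[left_idx + 1 : right_idx]
        intervals = tuple((e.start, e.end) for e in skipped)
        events.append(
            ASEvent(
                species_id=species_id,
                gene_id=gene.gene_id,
                event_type=ES,
                intervals=intervals,
                event_length=sum(e.length for e in skipped),
                region=classify_interval(gene, skipped[0].start, skipped[-1].end),
                contig_id=gene.contig_id,
            )
        )
    return events


def call_alt(
    passed: list[JunctionEvidence],
    annotation: Annotation,
    config: CallerConfig | None = None,
    species_id: str = "sample",
) -> list[ASEvent]:
    """Alternative donor/acceptor/position calls from novel junctions.

    A novel junction is compared against the annotated intron of its gene
    with maximal reciprocal overlap (ties: smaller total shift, then first
    intron in genomic order). Unassignable junctions are logged and skipped.
    """
    config = config or CallerConfig()
    events = []
    for j in passed:
        gene = _find_containing_gene(annotation, j.contig_id, j.intron_start - 1, j.intron_end + 1)
        if gene is None:
            continue
        introns = sorted(gene.introns, key=lambda i: i.start)
        if (j.intron_start, j.intron_end) in {(i.start, i.end) for i in introns}:
            continue  # constitutive
        exon_ends = {e.end for e in gene.exons}
        exon_starts = {e.start for e in gene.exons}
        if j.intron_start - 1 in exon_ends and j.intron_end + 1 in exon_starts:
            continue  # exon-skipping junction, handled by call_es
        best = None
        jlen = j.intron_end - j.intron_start + 1
        for intr in introns:
            ov = min(j.intron_end, intr.end) - max(j.intron_start, intr.start) + 1
            if ov <= 0:
                continue
            recip = min(ov / jlen, ov / intr.length)
            shift = abs(j.intron_start - intr.start) + abs(j.intron_end - intr.end)
            key = (-recip, shift, intr.start)
            if best is None or key < best[0]:
                best = (key, intr)
        if best is None:
            logger.warning(
                "junction %s:%d-%d in gene %s overlaps no annotated intron; skipped",
                j.contig_id, j.intron_start, j.intron_end, gene.gene_id,
            )
            continue
        ref = best[1]
        shift_start = j.intron_start - ref.start
        shift_end = j.intron_end - ref.end
        if shift_start != 0 and shift_end != 0:
            etype = ALTP
            length = abs(shift_start) + abs(shift_end)
        else:
            # which physical end varies, and is it the donor or the acceptor?
            varying_is_start = shift_start != 0
            donor_is_start = gene.strand == "+"
            donor_varies = varying_is_start == donor_is_start
            etype = ALTD if donor_varies else ALTA
            if config.swap_alt_labels:
                etype = ALTA if etype == ALTD else ALTD
            length = abs(shift_start) + abs(shift_end)
        events.append(
            ASEvent(
                species_id=species_id,
                gene_id=gene.gene_id,
                event_type=etype,
                intervals=((j.intron_start, j.intron_end),),
                event_length=length,
                region=classify_interval(gene, j.intron_start, j.intron_end),
                ref_junction=(ref.start, ref.end),
                contig_id=gene.contig_id,
            )
        )
    return events


def call_events(
    tables: EvidenceTables,
    annotation: Annotation,
    config: CallerConfig | None = None,
    species_id: str | None = None,
) -> list[ASEvent]:
    """Full per-species calling: filter junctions, then IR + ES + Alt events."""
    config = config or CallerConfig()
    species = species_id or tables.library.species_id
    passed, _rejected = filter_junctions(tables.junctions, config.policy, tables.library)
    events = call_ir(tables.intron_coverage, tables.library, annotation, config, species)
    events += call_es(passed, annotation, species)
    events += call_alt(passed, annotation, config, species)
    return sorted(events, key=lambda e: (e.gene_id, e.event_type, e.intervals))


def summarize_as(
    events_by_species: dict[str, list[ASEvent]],
    expressed_genes: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-species AS-type distribution and per-gene incidence.

    Returns one row per (species, event type) with counts and percentages,
    plus a ``genes_with_as`` / ``expressed_genes`` / ``prop_genes_with_as``
    summary when expressed-gene sets are supplied.
    """
    rows = []
    for species in sorted(events_by_species):
        events = events_by_species[species]
        total = len(events)
        genes = {e.gene_id for e in events}
        n_expressed = len(expressed_genes[species]) if expressed_genes else None
        for etype in EVENT_TYPES:
            n = sum(1 for e in events if e.event_type == etype)
            rows.append(
                {
                    "species_id": species,
                    "event_type": etype,
                    "n_events": n,
                    "percent": round(100.0 * n / total, 2) if total else 0.0,
                    "total_events": total,
                    "genes_with_as": len(genes),
                    "expressed_genes": n_expressed,
                    "prop_genes_with_as": (
                        round(len(genes) / n_expressed, 4)
                        if n_expressed
                        else (0.0 if expressed_genes is not None else None)
                    ),
                }
            )
    return pd.DataFrame(rows)
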