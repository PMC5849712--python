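"""Coding consequences of single-event genes: PTC and frameshift calls.

Eligibility mirrors the standard three-way screen: the gene carries
exactly one AS event, the event lies inside the coding region, and the
start codon is untouched. For eligible events the alternative coding
sequence is rebuilt from the genome (intron retained, exon(s) removed, or
junction boundaries shifted), translated in frame from the annotated
start, and scanned for a stop codon upstream of the one aligned to the
constitutive stop. A frameshift is a length change not divisible by 3;
no NMD positional rule is applied by default (an optional 50-nt rule is
available for exploration).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from ecas_splice.annotation_model import Annotation, CDS, GeneModel
from ecas_splice.as_caller import ALTA, ALTD, ALTP, ASEvent, ES, EVENT_TYPES, IR

ECAS_CLASS = "ECAS"
NON_ECAS_CLASS = "non-ECAS"


@dataclass(frozen=True)
class EligibilityCheck:
    single_event: bool
    in_cds: bool
    start_codon_intact: bool

    @property
    def eligible(self) -> bool:
        return self.single_event and self.in_cds and self.start_codon_intact


@dataclass(frozen=True)
class ConsequenceCall:
    gene_id: str
    event_type: str
    delta_len: int  # signed bases added(+)/removed(−) from the coding transcript
    frameshift: bool
    ptc: bool
    ptc_position: int | None  # 1-based codon index of the premature stop

    def __post_init__(self) -> None:
        if self.frameshift != (abs(self.delta_len) % 3 != 0):
            raise ValueError("frameshift flag inconsistent with delta_len")
        if self.ptc != (self.ptc_position is not None):
            raise ValueError("ptc_position must be set iff ptc")


def _affected_span(event: ASEvent) -> tuple[int, int]:
    positions = [p for iv in event.intervals for p in iv]
    if event.ref_junction is not None:
        positions.extend(event.ref_junction)
    return min(positions), max(positions)


def _start_codon_span(gene: GeneModel) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.cds_start, gene.cds_start + 2
    return gene.cds_end - 2, gene.cds_end


def check_eligibility(gene: GeneModel, events: list[ASEvent]) -> EligibilityCheck:
    """Screen one gene's events for consequence analysis."""
    single = len(events) == 1
    if not events:
        return EligibilityCheck(False, False, False)
    event = events[0]
    in_cds = event.region == CDS and gene.has_cds
    if gene.has_cds:
        s, e = _affected_span(event)
        cs, ce = _start_codon_span(gene)
        start_intact = not (s <= ce and cs <= e)
    else:
        start_intact = False
    return EligibilityCheck(single, in_cds, start_intact)


def _cds_exon_intervals(gene: GeneModel) -> list[list[int]]:
    out = []
    for exon in gene.exons:
        s, e = max(exon.start, gene.cds_start), min(exon.end, gene.cds_end)
        if s <= e:
            out.append([s, e])
    return out


def _apply_event(gene: GeneModel, event: ASEvent) -> list[list[int]]:
    """Exonic intervals of the alternative transcript, clipped to the CDS."""
    exons = [[e.start, e.end] for e in gene.exons]

    if event.event_type == IR:
        istart, iend = event.intervals[0]
        left = next((i for i, (s, e) in enumerate(exons) if e == istart - 1), None)
        right = next((i for i, (s, e) in enumerate(exons) if s == iend + 1), None)
        if left is None or right is None:
            raise ValueError(
                f"{gene.gene_id}: IR interval {istart}-{iend} is not an annotated intron"
            )
        merged = [exons[left][0], exons[right][1]]
        exons = exons[:left] + [merged] + exons[right + 1 :]
    elif event.event_type == ES:
        skipped = {tuple(iv) for iv in event.intervals}
        exons = [ex for ex in exons if tuple(ex) not in skipped]
        if len(exons) + len(skipped) != len(gene.exons):
            raise ValueError(f"{gene.gene_id}: ES intervals are not annotated exons")
    elif event.event_type in (ALTD, ALTA, ALTP):
        rstart, rend = event.ref_junction
        nstart, nend = event.intervals[0]
        left = next((i for i, (s, e) in enumerate(exons) if e == rstart - 1), None)
        right = next((i for i, (s, e) in enumerate(exons) if s == rend + 1), None)
        if left is None or right is None:
            raise ValueError(
                f"{gene.gene_id}: reference junction {rstart}-{rend} is not an annotated intron"
            )
        exons[left][1] = nstart - 1
        exons[right][0] = nend + 1
        if exons[left][0] > exons[left][1] or exons[right][0] > exons[right][1]:
            raise ValueError(f"{gene.gene_id}: junction shift consumes a whole exon")
    else:
        raise ValueError(f"unsupported event type {event.event_type}")

    clipped = []
    for s, e in exons:
        cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
        if cs <= ce:
            clipped.append([cs, ce])
    return clipped


def constitutive_cds(gene: GeneModel, annotation: Annotation) -> str:
    """The annotated coding sequence, transcription direction."""
    seq = "".join(
        annotation.sequence(gene.contig_id, s, e) for s, e in _cds_exon_intervals(gene)
    )
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def build_alt_cds(gene: GeneModel, event: ASEvent, annotation: Annotation) -> str:
    """Alternative coding sequence with the event applied, transcription direction."""
    if not gene.has_cds:
        raise ValueError(f"{gene.gene_id}: no CDS")
    s, e = _affected_span(event)
    if not gene.contains(s, e):
        raise ValueError(f"{gene.gene_id}: event interval outside gene span")
    seq = "".join(
        annotation.sequence(gene.contig_id, s, e) for s, e in _apply_event(gene, event)
    )
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def call_consequence(alt_cds: str, constitutive: str, gene_id: str = "", event_type: str = "") -> ConsequenceCall:
    """Translate the alternative CDS and flag PTC / frameshift.

    A PTC is a stop codon whose codon ends strictly before the end of the
    alternative coding sequence — i.e. upstream of the codon aligned to
    the constitutive stop (under a frameshift the constitutive stop is
    never in frame, so any in-frame stop is premature).
    """
    for name, seq in (("alternative", alt_cds), ("constitutive", constitutive)):
        if not seq.startswith("ATG"):
            raise ValueError(f"{gene_id or 'gene'}: {name} CDS does not start with ATG")
    delta = len(alt_cds) - len(constitutive)
    frameshift = abs(delta) % 3 != 0

    protein = str(Seq(alt_cds[: len(alt_cds) - len(alt_cds) % 3]).translate())
    stop_idx = protein.find("*")
    ptc = stop_idx >= 0 and 3 * (stop_idx + 1) < len(alt_cds)
    return ConsequenceCall(
        gene_id=gene_id,
        event_type=event_type,
        delta_len=delta,
        frameshift=frameshift,
        ptc=ptc,
        ptc_position=stop_idx + 1 if ptc else None,
    )


def consequence_tables(
    labeled_calls: list[tuple[ConsequenceCall, str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PTC and frameshift contingency tables by AS type and conservation class.

    ``labeled_calls`` pairs each call with its class ("ECAS"/"non-ECAS").
    Percentages are count / row-pair total × 100, rounded to 2 decimals;
    an empty type × class cell yields a zero row with 0.00%.
    """
    classes = (ECAS_CLASS, NON_ECAS_CLASS)
    columns = list(EVENT_TYPES) + ["Total"]

    def one_table(flag_of) -> pd.DataFrame:
        rows = []
        for cls in classes:
            calls = [c for c, label in labeled_calls if label == cls]
            for col in columns:
                subset = calls if col == "Total" else [c for c in calls if c.event_type == col]
                n_yes = sum(1 for c in subset if flag_of(c))
                n_no = len(subset) - n_yes
                total = n_yes + n_no
                rows.append(
                    {
                        "class": cls,
                        "event_type": col,
                        "n_yes": n_yes,
                        "pct_yes": round(100.0 * n_yes / total, 2) if total else 0.0,
                        "n_no": n_no,
                        "pct_no": round(100.0 * n_no / total, 2) if total else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    ptc_table = one_table(lambda c: c.ptc)
    fs_table = one_table(lambda c: c.frameshift)
    return ptc_table, fs_table
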