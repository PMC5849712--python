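"""Reliability filtering and genomic-context classification of splice junctions.

A junction is kept when (1) its read support reaches at least
``min_support_per_10M`` reads per ten million totally mapped reads (never
below that absolute minimum), (2) every supporting read overhangs the
junction by at least ``min_overhang`` bases on both sides, and (3) at
least ``min_distinct_nonrepetitive`` supporting reads have a
non-repetitive match position — read here as uniquely aligned AND starting
at distinct genomic coordinates, the strictest plausible reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ecas_splice.alignment_evidence import JunctionEvidence, LibraryStats
from ecas_splice.annotation_model import Annotation, INTERGENIC, classify_interval

REASON_SUPPORT = "support"
REASON_OVERHANG = "overhang"
REASON_DISTINCT = "distinct_positions"
REASON_UNIQUE = "unique_support"


@dataclass(frozen=True)
class FilterPolicy:
    min_support_per_10M: int = 2
    min_overhang: int = 8
    min_distinct_nonrepetitive: int = 2

    def __post_init__(self) -> None:
        if min(self.min_support_per_10M, self.min_overhang, self.min_distinct_nonrepetitive) < 1:
            raise ValueError("all policy thresholds must be >= 1")


def support_threshold(policy: FilterPolicy, library: LibraryStats) -> int:
    """Required read support, scaled to library depth.

    ceil(min_support_per_10M × total_mapped / 1e7), floored at the stated
    absolute minimum so shallow libraries are never filtered more loosely.
    Monotone in total_mapped.
    """
    if library.total_mapped_reads <= 0:
        raise ValueError("library has zero mapped reads")
    scaled = math.ceil(policy.min_support_per_10M * library.total_mapped_reads / 1e7)
    return max(policy.min_support_per_10M, scaled)


def filter_junctions(
    junctions: list[JunctionEvidence],
    policy: FilterPolicy,
    library: LibraryStats,
) -> tuple[list[JunctionEvidence], list[tuple[JunctionEvidence, str]]]:
    """Partition junctions into (passed, rejected-with-first-failed-reason)."""
    threshold = support_threshold(policy, library)
    passed: list[JunctionEvidence] = []
    rejected: list[tuple[JunctionEvidence, str]] = []
    for j in junctions:
        if j.support_reads < threshold:
            rejected.append((j, REASON_SUPPORT))
        elif j.min_overhang < policy.min_overhang:
            rejected.append((j, REASON_OVERHANG))
        elif j.distinct_positions < policy.min_distinct_nonrepetitive:
            rejected.append((j, REASON_DISTINCT))
        elif j.unique_support < policy.min_distinct_nonrepetitive:
            rejected.append((j, REASON_UNIQUE))
        else:
            passed.append(j)
    return passed, rejected


def classify_junctions(
    junctions: list[JunctionEvidence], annotation: Annotation
) -> tuple[list[tuple[JunctionEvidence, str, str]], pd.DataFrame]:
    """Label each junction by its genomic context.

    The label is taken from the regions of the two exonic bases flanking
    the gap (intron_start − 1 and intron_end + 1) within the containing
    gene; junctions outside every gene's span are intergenic. When several
    genes contain the junction the lexicographically smallest gene_id wins
    (deterministic output).

    Returns (per-junction rows (evidence, gene_id-or-'', label), summary
    counts per label).
    """
    rows: list[tuple[JunctionEvidence, str, str]] = []
    for j in junctions:
        left, right = j.intron_start - 1, j.intron_end + 1
        gene_hit = None
        for gene in annotation.genes_overlapping(j.contig_id, left, right):
            if gene.contains(left, right):
                gene_hit = gene
                break
        if gene_hit is None:
            rows.append((j, "", INTERGENIC))
        else:
            rows.append((j, gene_hit.gene_id, classify_interval(gene_hit, left, right)))

    counts = pd.Series([label for _, _, label in rows], dtype="object").value_counts()
    total = len(rows)
    summary = pd.DataFrame(
        {
            "region": counts.index,
            "n_junctions": counts.values,
            "percent": [round(100.0 * c / total, 2) if total else 0.0 for c in counts.values],
        }
    )
    return rows, summary
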