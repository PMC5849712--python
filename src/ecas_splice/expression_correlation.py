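"""Per-gene expression (RPKM) and AS-incidence vs genic-feature trends.

RPKM = exonic reads × 1e9 / (exonic model length × total mapped reads),
computed on the longest gene model with unique/primary alignments only
(no multiread rescue). Trends are estimated by binning genes into feature
quantiles and regressing the per-bin proportion of genes carrying the
focal event type on the bin midpoint (ordinary least squares, t-test on
the slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ecas_splice.alignment_evidence import LibraryStats
from ecas_splice.annotation_model import Annotation
from ecas_splice.as_caller import ASEvent


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    exonic_read_count: int
    exonic_length_bp: int
    rpkm: float
    expressed: bool


@dataclass(frozen=True)
class BinnedTrend:
    feature: str
    bin_midpoints: tuple[float, ...]
    proportions: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    p_value: float


FEATURES = ("rpkm", "intron_number", "intron_length", "exon_number", "exon_length")


def compute_rpkm(
    exon_counts: dict[str, int], annotation: Annotation, library: LibraryStats
) -> list[ExpressionRecord]:
    records = []
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        length = gene.exonic_length
        if length <= 0:
            raise ValueError(f"gene {gene_id}: zero-length exon model")
        count = exon_counts.get(gene_id, 0)
        rpkm = count * 1e9 / (length * library.total_mapped_reads)
        records.append(ExpressionRecord(gene_id, count, length, rpkm, count >= 1))
    return records


def _gene_feature(gene, feature: str, events: list[ASEvent]) -> float:
    introns = gene.introns
    if feature == "intron_number":
        return float(len(introns))
    if feature == "exon_number":
        return float(len(gene.exons))
    if feature == "intron_length":
        return float(np.mean([i.length for i in introns])) if introns else np.nan
    if feature == "exon_length":
        return float(np.mean([e.length for e in gene.exons]))
    raise ValueError(f"unknown feature {feature}")


def trend_vs_feature(
    events: list[ASEvent],
    annotation: Annotation,
    feature: str,
    expression: list[ExpressionRecord] | None = None,
    event_type: str | None = None,
    n_bins: int = 10,
    expressed_only: bool = True,
) -> BinnedTrend:
    """Proportion of genes with a qualifying event, across feature quantile bins.

    ``feature`` is one of rpkm / intron_number / intron_length /
    exon_number / exon_length (lengths are per-gene means). Genes are cut
    into ``n_bins`` quantile bins; bins collapsing to fewer than two
    distinct edges are an error (degenerate binning).
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    expr_map = {r.gene_id: r for r in expression} if expression else {}
    qualifying = {
        e.gene_id for e in events if event_type is None or e.event_type == event_type
    }

    rows = []
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        if expressed_only and expression is not None and not expr_map[gene_id].expressed:
            continue
        if feature == "rpkm":
            if not expression:
                raise ValueError("rpkm feature requires expression records")
            value = expr_map[gene_id].rpkm
        else:
            value = _gene_feature(gene, feature, events)
        if np.isnan(value):
            continue
        rows.append((value, gene_id in qualifying))
    df = pd.DataFrame(rows, columns=["value", "has_event"])
    if df.empty:
        raise ValueError("no genes available for binning")

    try:
        df["bin"] = pd.qcut(df["value"], q=n_bins, duplicates="drop")
    except ValueError as exc:
        raise ValueError("degenerate binning: all genes fall in one bin") from exc
    grouped = df.groupby("bin", observed=True)
    mids = np.array([interval.mid for interval in grouped.groups.keys()], dtype=float)
    props = grouped["has_event"].mean().to_numpy(dtype=float)
    if len(mids) < 2:
        raise ValueError("degenerate binning: all genes fall in one bin")

    fit = stats.linregress(mids, props)
    return BinnedTrend(
        feature=feature,
        bin_midpoints=tuple(mids),
        proportions=tuple(props),
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.rvalue**2,
        p_value=fit.pvalue,
    )


def expression_table(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.exonic_read_count, r.exonic_length_bp, round(r.rpkm, 4), r.expressed)
            for r in records
        ],
        columns=["gene_id", "exonic_reads", "exonic_length_bp", "rpkm", "expressed"],
    )


def trend_table(trend: BinnedTrend) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "feature": trend.feature,
            "bin_midpoint": trend.bin_midpoints,
            "proportion_with_event": trend.proportions,
        }
    )
    df["slope"] = trend.slope
    df["r_squared"] = trend.r_squared
    df["p_value"] = trend.p_value
    return df
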