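"""Reference genome and gene-model handling.

All public coordinates are GFF3-native: 1-based, inclusive at both ends.
Genes with several mRNA models are reduced to the longest model (sum of
exon lengths), so every downstream stage sees exactly one exon/intron
structure per gene, mirroring the "longest gene model" convention used for
expression and splicing analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO
from intervaltree import IntervalTree

VALID_ALPHABET = set("ACGTN")

# genic-region labels; exactly one applies to any queried interval
CDS = "CDS"
UTR5 = "5UTR"
UTR3 = "3UTR"
UTR5_CDS = "5UTR-CDS"
CDS_UTR3 = "CDS-3UTR"
INTERGENIC = "intergenic"

GENIC_REGION_LABELS = (CDS, UTR5, UTR3, UTR5_CDS, CDS_UTR3, INTERGENIC)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon; ``rank`` counts along transcription direction (1-based)."""

    contig_id: str
    start: int
    end: int
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"exon start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IntronInterval:
    """Intronic bases between two consecutive exons.

    ``donor_pos`` is the intron boundary adjacent to the upstream exon in
    transcription direction (the 5' splice site); ``acceptor_pos`` the
    boundary adjacent to the downstream exon (3' splice site). On the '+'
    strand donor_pos == start; on '-' they are mirrored.
    """

    contig_id: str
    start: int
    end: int
    donor_pos: int
    acceptor_pos: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"intron start {self.start} > end {self.end}")
        if {self.donor_pos, self.acceptor_pos} != {self.start, self.end}:
            raise AnnotationError("donor/acceptor must be the intron bounds")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """One gene's exon/CDS structure (its longest mRNA model)."""

    gene_id: str
    contig_id: str
    strand: str
    exons: list[ExonInterval]
    cds_start: int
    cds_end: int
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if prev_end is not None and exon.start <= prev_end:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
            prev_end = exon.end
        # re-rank along transcription direction
        ordered = self.exons if self.strand == "+" else list(reversed(self.exons))
        self.exons = sorted(
            [
                ExonInterval(e.contig_id, e.start, e.end, rank=i + 1)
                for i, e in enumerate(ordered)
            ],
            key=lambda e: e.start,
        )
        if self.has_cds:
            if not (self.span_start <= self.cds_start <= self.cds_end <= self.span_end):
                raise AnnotationError(
                    f"{self.gene_id}: CDS [{self.cds_start}..{self.cds_end}] outside "
                    f"exon span [{self.span_start}..{self.span_end}]"
                )

    @property
    def has_cds(self) -> bool:
        return self.cds_start > 0 and self.cds_end > 0

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> list[IntronInterval]:
        return derive_introns(self)

    def contains(self, start: int, end: int) -> bool:
        return self.span_start <= start and end <= self.span_end


#: Annotation = gene models plus contig sequences and a per-contig gene index
@dataclass
class Annotation:
    genes: dict[str, GeneModel]
    contigs: dict[str, str] = field(default_factory=dict)
    _gene_index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for contig, seq in self.contigs.items():
            if not seq:
                raise AnnotationError(f"contig {contig}: empty sequence")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise AnnotationError(f"contig {contig}: invalid characters {sorted(bad)}")
        self._gene_index = {}
        for gene in self.genes.values():
            tree = self._gene_index.setdefault(gene.contig_id, IntervalTree())
            tree.addi(gene.span_start, gene.span_end + 1, gene.gene_id)

    def genes_overlapping(self, contig_id: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span overlaps [start, end], ordered by gene_id."""
        tree = self._gene_index.get(contig_id)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end + 1))
        return [self.genes[g] for g in hits]

    def sequence(self, contig_id: str, start: int, end: int) -> str:
        """Genomic sequence for a 1-based inclusive interval (forward strand)."""
        seq = self.contigs[contig_id]
        if not (1 <= start <= end <= len(seq)):
            raise AnnotationError(
                f"interval [{start}..{end}] outside contig {contig_id} (len {len(seq)})"
            )
        return seq[start - 1 : end]


def derive_introns(gene: GeneModel) -> list[IntronInterval]:
    """Introns as gaps between consecutive exons, in transcription order.

    A single-exon gene yields an empty list.
    """
    exons = gene.exons  # genomic order
    gaps = []
    for left, right in zip(exons, exons[1:]):
        start, end = left.end + 1, right.start - 1
        if gene.strand == "+":
            donor, acceptor = start, end
        else:
            donor, acceptor = end, start
        gaps.append(IntronInterval(gene.contig_id, start, end, donor, acceptor))
    if gene.strand == "-":
        gaps.reverse()  # transcription direction
    return gaps


def _point_region(gene: GeneModel, pos: int) -> str | None:
    """Region of a single position relative to a gene, or None if outside the span."""
    if not (gene.span_start <= pos <= gene.span_end):
        return None
    if not gene.has_cds:
        return None
    if gene.cds_start <= pos <= gene.cds_end:
        return CDS
    upstream = pos < gene.cds_start  # genomic left of the CDS
    if gene.strand == "+":
        return UTR5 if upstream else UTR3
    return UTR3 if upstream else UTR5


def classify_interval(gene: GeneModel | None, start: int, end: int) -> str:
    """Classify an interval as CDS / 5UTR / 3UTR / spanning / intergenic.

    The label is decided by where the two interval ends fall relative to
    the gene's CDS bounds. Intervals outside the gene span (or with no
    gene supplied) are intergenic; a coding-less gene yields intergenic
    for consequence purposes. An interval spanning the entire CDS (one
    end in each UTR) is labeled 5UTR-CDS, the first transition met in
    transcription direction.
    """
    if start > end:
        start, end = end, start
    if gene is None:
        return INTERGENIC
    a = _point_region(gene, start)
    b = _point_region(gene, end)
    if a is None or b is None:
        return INTERGENIC
    if a == b:
        return a
    regions = {a, b}
    if regions == {UTR5, CDS}:
        return UTR5_CDS
    if regions == {CDS, UTR3}:
        return CDS_UTR3
    return UTR5_CDS  # spans the whole CDS: 5'UTR on one end, 3'UTR on the other


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O


def _parse_gff3(handle: Iterable[str]) -> tuple[list[dict], dict[str, list[int]]]:
    """Parse GFF3 features we care about; returns feature dicts."""
    features = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        contig, _source, ftype, start, end, _score, strand, _phase, attrs = cols
        if ftype not in {"gene", "mRNA", "exon", "CDS"}:
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise AnnotationError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        if start_i > end_i or start_i < 1:
            raise AnnotationError(f"GFF3 line {lineno}: invalid interval {start}..{end}")
        attr_map = {}
        for item in attrs.split(";"):
            item = item.strip()
            if item and "=" in item:
                key, val = item.split("=", 1)
                attr_map[key] = val
        features.append(
            {
                "contig": contig,
                "type": ftype,
                "start": start_i,
                "end": end_i,
                "strand": strand,
                "id": attr_map.get("ID", ""),
                "parent": attr_map.get("Parent", ""),
                "lineno": lineno,
            }
        )
    return features, {}


def load_annotation(genome_path, gff_path) -> Annotation:
    """Load FASTA + GFF3 into an :class:`Annotation`.

    Genes with several mRNA models keep only the longest one (sum of exon
    lengths; ties broken by lexicographically smallest model id). A CDS
    feature outside its model's exon span raises a validation error naming
    the gene.
    """
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_path), "fasta")
    }

    with open(gff_path) as handle:
        features, _ = _parse_gff3(handle)

    genes_meta = {f["id"]: f for f in features if f["type"] == "gene"}
    mrnas = {f["id"]: f for f in features if f["type"] == "mRNA"}
    exons_by_mrna: dict[str, list[dict]] = {}
    cds_by_mrna: dict[str, list[dict]] = {}
    for f in features:
        if f["type"] == "exon":
            exons_by_mrna.setdefault(f["parent"], []).append(f)
        elif f["type"] == "CDS":
            cds_by_mrna.setdefault(f["parent"], []).append(f)

    # pick the longest model per gene
    models_by_gene: dict[str, list[str]] = {}
    for mid, mrna in mrnas.items():
        models_by_gene.setdefault(mrna["parent"], []).append(mid)

    genes: dict[str, GeneModel] = {}
    for gene_id, model_ids in sorted(models_by_gene.items()):
        def model_len(mid: str) -> int:
            return sum(f["end"] - f["start"] + 1 for f in exons_by_mrna.get(mid, []))

        best = sorted(model_ids, key=lambda m: (-model_len(m), m))[0]
        mrna = mrnas[best]
        exon_feats = sorted(exons_by_mrna.get(best, []), key=lambda f: f["start"])
        if not exon_feats:
            raise AnnotationError(f"gene {gene_id}: model {best} has no exons")
        exons = [
            ExonInterval(f["contig"], f["start"], f["end"]) for f in exon_feats
        ]
        cds_feats = cds_by_mrna.get(best, [])
        if cds_feats:
            cds_start = min(f["start"] for f in cds_feats)
            cds_end = max(f["end"] for f in cds_feats)
            for f in cds_feats:
                if not any(e["start"] <= f["start"] and f["end"] <= e["end"] for e in exon_feats):
                    raise AnnotationError(
                        f"gene {gene_id}: CDS [{f['start']}..{f['end']}] outside exon span"
                    )
        else:
            cds_start = cds_end = 0
        meta = genes_meta.get(gene_id, mrna)
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            contig_id=meta["contig"],
            strand=meta["strand"],
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            model_id=best,
        )

    return Annotation(genes=genes, contigs=contigs)


def write_gff3(annotation: Annotation, path) -> None:
    """Write the (longest-model) annotation back to GFF3."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene_id in sorted(annotation.genes):
            gene = annotation.genes[gene_id]
            cols = lambda ftype, s, e, attrs: "\t".join(  # noqa: E731
                [gene.contig_id, "ecas_splice", ftype, str(s), str(e), ".", gene.strand, ".", attrs]
            )
            out.write(cols("gene", gene.span_start, gene.span_end, f"ID={gene.gene_id}") + "\n")
            mid = gene.model_id or f"{gene.gene_id}.1"
            out.write(
                cols("mRNA", gene.span_start, gene.span_end, f"ID={mid};Parent={gene.gene_id}")
                + "\n"
            )
            for exon in gene.exons:
                out.write(cols("exon", exon.start, exon.end, f"Parent={mid}") + "\n")
            if gene.has_cds:
                for exon in gene.exons:
                    s = max(exon.start, gene.cds_start)
                    e = min(exon.end, gene.cds_end)
                    if s <= e:
                        out.write(cols("CDS", s, e, f"Parent={mid}") + "\n")


def write_fasta(contigs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as out:
        for contig_id in sorted(contigs):
            out.write(f">{contig_id}\n")
            seq = contigs[contig_id]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def annotation_summary(annotation: Annotation):
    """Per-gene summary rows: gene_id, n_exons, n_introns, cds_len."""
    import pandas as pd

    rows = []
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        cds_len = 0
        if gene.has_cds:
            for exon in gene.exons:
                s = max(exon.start, gene.cds_start)
                e = min(exon.end, gene.cds_end)
                if s <= e:
                    cds_len += e - s + 1
        rows.append(
            {
                "gene_id": gene_id,
                "n_exons": len(gene.exons),
                "n_introns": max(len(gene.exons) - 1, 0),
                "cds_len": cds_len,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_exons", "n_introns", "cds_len"])
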