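"""Seeded synthetic genomes, annotations and multi-species read evidence.

The generator emulates the layout of a multi-species splicing study on a
single shared reference: one genome + gene-model annotation, several
"species" read sets aligned against it, alternative-splicing events
planted per species with a controlled overlap design across species, and
known coding-consequence labels. Reads are emitted directly as alignments
(SAM) because the pipeline consumes alignments, not raw reads.

Planted genes follow the canonical coding-gene grammar: GT..AG introns,
ATG start, a single in-frame stop at the CDS end and no internal in-frame
stop in the constitutive CDS. Every planted event lies inside the CDS of
its gene and leaves the start codon untouched, so all planted events are
eligible for consequence calling; the generator computes the intended
PTC/frameshift labels with its own translation oracle (a hand-held codon
table), independent of the consequence-calling code path it is used to
test.
"""

from __future__ import annotations


from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ecas_splice.alignment_evidence import (
    EvidenceTables,
    IntronCoverage,
    JunctionEvidence,
    LibraryStats,
    write_evidence_tables,
)
from ecas_splice.annotation_model import (
    Annotation,
    ExonInterval,
    GeneModel,
    write_fasta,
    write_gff3,
)
from ecas_splice.as_caller import ALTA, ALTD, ALTP, ASEvent, ES, IR

# standard genetic code, TCAG order (independent of Bio.Seq on purpose:
# this module is the oracle the consequence caller is tested against)
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa == "*"))
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Generator-side translation oracle (standard nuclear code)."""
    return "".join(
        CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate a four-species,
    root-transcriptome-like design at desk scale."""

    seed: int = 0
    n_genes: int = 200
    n_species: int = 4
    exon_count_range: tuple[int, int] = (2, 7)
    exon_length_range: tuple[int, int] = (60, 180)
    intron_length_range: tuple[int, int] = (60, 150)
    utr5_range: tuple[int, int] = (15, 40)
    utr3_range: tuple[int, int] = (15, 40)
    as_gene_fraction: float = 0.5  # fraction of genes carrying one planted event
    event_type_rates: dict = field(
        default_factory=lambda: {IR: 0.68, ALTA: 0.13, ALTP: 0.10, ALTD: 0.05, ES: 0.04}
    )
    conservation_design: dict = field(
        default_factory=lambda: {1: 0.55, 2: 0.20, 3: 0.15, 4: 0.10}
    )
    read_length: int = 75
    junction_support: int = 4  # spliced reads per planted junction ("depth")
    expression_reads_per_gene: int = 3
    noise_junction_rate: float = 0.0  # noise junctions per planted event
    frac_ir_len_div3: float = 0.5  # fraction of intron lengths made divisible by 3
    min_gap: int = 20
    genes_per_contig: int = 100
    spacer: int = 150

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_species < 1:
            raise SimulationError("n_genes and n_species must be positive")
        if not 0.0 <= self.as_gene_fraction <= 1.0:
            raise SimulationError("as_gene_fraction must be in [0, 1]")
        for rate in self.event_type_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("event type rates must be in [0, 1]")
        if self.exon_length_range[0] < 55 or self.intron_length_range[0] < 40:
            raise SimulationError(
                "exons must be >= 55 bp and introns >= 40 bp to satisfy "
                "codon/overhang constraints"
            )
        if max(self.conservation_design) > self.n_species:
            raise SimulationError("conservation design references more species than exist")

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


@dataclass
class _GeneBuild:
    """Transcript-space view of one simulated gene."""

    gene_id: str
    contig_id: str
    strand: str
    g_start: int  # genomic 1-based start of the gene block
    length: int  # gene block length
    exon_seqs: list[str]  # transcription order
    intron_seqs: list[str]
    utr5: int
    utr3: int
    cds: str  # constitutive coding sequence (starts ATG, ends on a stop)
    exon_local: list[tuple[int, int]]  # transcription order, local 1-based
    genomic_exons: list[tuple[int, int]]  # transcription order
    genomic_introns: list[tuple[int, int]]  # transcription order

    @property
    def cum_exon(self) -> list[int]:
        out, total = [], 0
        for seq in self.exon_seqs:
            total += len(seq)
            out.append(total)
        return out

    def cds_pos_after_exon(self, t: int) -> int:
        """0-based CDS offset of the junction following transcription-exon t."""
        return self.cum_exon[t] - self.utr5


@dataclass
class SimulatedReference:
    annotation: Annotation
    builds: dict[str, _GeneBuild]
    config: SimulationConfig


@dataclass(frozen=True)
class PlantedEvent:
    """One planted event signature plus its intended outcomes."""

    gene_id: str
    contig_id: str
    event_type: str
    intervals: tuple[tuple[int, int], ...]
    ref_junction: tuple[int, int] | None
    event_length: int
    region: str
    species_set: frozenset[str]
    delta_len: int
    frameshift: bool
    ptc: bool
    ptc_position: int | None
    alt_cds: str  # the intended alternative coding sequence

    def as_event(self, species_id: str) -> ASEvent:
        return ASEvent(
            species_id=species_id,
            gene_id=self.gene_id,
            event_type=self.event_type,
            intervals=self.intervals,
            event_length=self.event_length,
            region=self.region,
            ref_junction=self.ref_junction,
            contig_id=self.contig_id,
        )


@dataclass
class GroundTruth:
    events: list[PlantedEvent]
    config: SimulationConfig

    def events_for(self, species_id: str) -> list[ASEvent]:
        return sorted(
            (e.as_event(species_id) for e in self.events if species_id in e.species_set),
            key=lambda e: (e.gene_id, e.event_type, e.intervals),
        )

    def signatures_for(self, species_id: str) -> set[tuple]:
        return {e.signature for e in self.events_for(species_id)}


# ---------------------------------------------------------------------------
# reference simulation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _map_local(build_strand: str, g_start: int, length: int, s: int, e: int) -> tuple[int, int]:
    """Map a local (transcription-orientation) interval to genomic coordinates."""
    if build_strand == "+":
        return g_start + s - 1, g_start + e - 1
    return g_start + (length - e), g_start + (length - s)


def simulate_reference(config: SimulationConfig) -> SimulatedReference:
    """Generate the genome and annotation; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, list[str]] = {}
    contig_pos: dict[str, int] = {}
    genes: dict[str, GeneModel] = {}
    builds: dict[str, _GeneBuild] = {}

    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:05d}"
        contig_id = f"chr{gi // config.genes_per_contig + 1}"
        parts = contigs.setdefault(contig_id, [])
        if contig_id not in contig_pos:
            spacer = _random_seq(rng, config.spacer)
            parts.append(spacer)
            contig_pos[contig_id] = config.spacer

        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1))
            for _ in range(n_exons)
        ]
        intron_lens = []
        for _ in range(n_exons - 1):
            ilen = int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
            if rng.random() < config.frac_ir_len_div3:
                ilen += (3 - ilen % 3) % 3
            elif ilen % 3 == 0:
                ilen += 1
            intron_lens.append(ilen)
        u5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        u3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        total_exonic = sum(exon_lens)
        cds_len = total_exonic - u5 - u3
        u3 += cds_len % 3
        cds_len -= cds_len % 3
        if cds_len < 9 or exon_lens[0] < u5 + 6 or exon_lens[-1] < u3 + 6:
            raise SimulationError(
                f"{gene_id}: exon/UTR ranges leave no room for a coding sequence"
            )

        n_mid = cds_len // 3 - 2
        cds = (
            "ATG"
            + "".join(rng.choice(SENSE_CODONS) for _ in range(n_mid))
            + str(rng.choice(STOP_CODONS))
        )
        transcript = _random_seq(rng, u5) + cds + _random_seq(rng, u3)

        exon_seqs, pos = [], 0
        for elen in exon_lens:
            exon_seqs.append(transcript[pos : pos + elen])
            pos += elen
        intron_seqs = ["GT" + _random_seq(rng, ilen - 4) + "AG" for ilen in intron_lens]

        # local plus-orientation layout
        local_seq_parts, exon_local, cursor = [], [], 0
        for k, eseq in enumerate(exon_seqs):
            exon_local.append((cursor + 1, cursor + len(eseq)))
            local_seq_parts.append(eseq)
            cursor += len(eseq)
            if k < len(intron_seqs):
                local_seq_parts.append(intron_seqs[k])
                cursor += len(intron_seqs[k])
        local_seq = "".join(local_seq_parts)
        length = len(local_seq)

        strand = "+" if rng.random() < 0.5 else "-"
        g_start = contig_pos[contig_id] + 1
        genomic_seq = local_seq if strand == "+" else revcomp(local_seq)
        parts.append(genomic_seq)
        parts.append(_random_seq(rng, config.spacer))
        contig_pos[contig_id] += length + config.spacer

        genomic_exons = [
            _map_local(strand, g_start, length, s, e) for s, e in exon_local
        ]
        cds_local = (u5 + 1, total_exonic - u3)
        # CDS bounds live inside the first/last exon, so intron offsets cancel:
        # map transcript coords to local coords through the exon layout
        def transcript_to_local(tp: int) -> int:
            run = 0
            for (ls, _le), eseq in zip(exon_local, exon_seqs):
                if tp <= run + len(eseq):
                    return ls + (tp - run) - 1
                run += len(eseq)
            raise SimulationError("transcript position outside exons")

        p1 = _map_local(strand, g_start, length, transcript_to_local(cds_local[0]),
                        transcript_to_local(cds_local[0]))[0]
        p2 = _map_local(strand, g_start, length, transcript_to_local(cds_local[1]),
                        transcript_to_local(cds_local[1]))[0]
        cds_g = sorted((p1, p2))

        gene = GeneModel(
            gene_id=gene_id,
            contig_id=contig_id,
            strand=strand,
            exons=[ExonInterval(contig_id, s, e) for s, e in genomic_exons],
            cds_start=cds_g[0],
            cds_end=cds_g[1],
            model_id=f"{gene_id}.1",
        )
        genes[gene_id] = gene
        builds[gene_id] = _GeneBuild(
            gene_id=gene_id,
            contig_id=contig_id,
            strand=strand,
            g_start=g_start,
            length=length,
            exon_seqs=exon_seqs,
            intron_seqs=intron_seqs,
            utr5=u5,
            utr3=u3,
            cds=cds,
            exon_local=exon_local,
            genomic_exons=genomic_exons,
            genomic_introns=[
                (i.start, i.end) for i in gene.introns  # already transcription order
            ],
        )

    annotation = Annotation(
        genes=genes, contigs={c: "".join(parts) for c, parts in contigs.items()}
    )
    return SimulatedReference(annotation=annotation, builds=builds, config=config)


# ---------------------------------------------------------------------------
# event planting


def _intended_consequence(alt_cds: str, const_cds: str) -> tuple[int, bool, bool, int | None]:
    delta = len(alt_cds) - len(const_cds)
    frameshift = abs(delta) % 3 != 0
    protein = translate(alt_cds)
    stop = protein.find("*")
    ptc = stop >= 0 and 3 * (stop + 1) < len(alt_cds)
    return delta, frameshift, ptc, (stop + 1 if ptc else None)


def _plant_one(
    build: _GeneBuild, etype: str, rng: np.random.Generator
) -> tuple[tuple[tuple[int, int], ...], tuple[int, int] | None, int, str] | None:
    """Plant one event of ``etype`` on a gene; returns
    (intervals, ref_junction, event_length, alt_cds) or None if infeasible."""
    n_exons = len(build.exon_seqs)
    strand = build.strand

    if etype == ES:
        if n_exons < 3:
            return None
        k = int(rng.integers(1, n_exons - 1))  # internal exon, transcription order
        exon_len = len(build.exon_seqs[k])
        pos = build.cds_pos_after_exon(k - 1)
        alt = build.cds[:pos] + build.cds[pos + exon_len :]
        interval = tuple(sorted(build.genomic_exons[k]))
        return (interval,), None, exon_len, alt

    if n_exons < 2:
        return None
    t = int(rng.integers(0, n_exons - 1))  # intron index, transcription order
    intron_seq = build.intron_seqs[t]
    ilen = len(intron_seq)
    gs, ge = build.genomic_introns[t]
    pos = build.cds_pos_after_exon(t)

    if etype == IR:
        alt = build.cds[:pos] + intron_seq + build.cds[pos:]
        return ((gs, ge),), None, ilen, alt

    if etype == ALTP:
        dmax = min(12, ilen // 5)
        if dmax < 6:
            return None
        d_donor = int(rng.integers(6, dmax + 1))
        d_acc = int(rng.integers(6, dmax + 1))
        alt = build.cds[:pos] + intron_seq[:d_donor] + intron_seq[-d_acc:] + build.cds[pos:]
        if strand == "+":
            novel = (gs + d_donor, ge - d_acc)
        else:
            novel = (gs + d_acc, ge - d_donor)
        return (novel,), (gs, ge), d_donor + d_acc, alt

    # AltD / AltA: one end varies; shift direction into the intron (insertion)
    # or into the flanking exon (deletion), chosen at random where feasible
    donor_side = etype == ALTD
    into_intron = rng.random() < 0.7
    if into_intron:
        dmax = min(15, ilen // 4, ilen - 25)
        if dmax < 3:
            return None
        d = int(rng.integers(3, dmax + 1))
        if donor_side:
            alt = build.cds[:pos] + intron_seq[:d] + build.cds[pos:]
            novel = (gs + d, ge) if strand == "+" else (gs, ge - d)
        else:
            alt = build.cds[:pos] + intron_seq[-d:] + build.cds[pos:]
            novel = (gs, ge - d) if strand == "+" else (gs + d, ge)
    else:
        if donor_side:
            avail = pos - 4  # keep the start codon plus margin intact
        else:
            avail = len(build.cds) - pos - 4  # keep the stop codon region
        exon_room = (
            len(build.exon_seqs[t]) - (build.utr5 + 6 if t == 0 else 6)
            if donor_side
            else len(build.exon_seqs[t + 1]) - (build.utr3 + 6 if t + 1 == len(build.exon_seqs) - 1 else 6)
        )
        dmax = min(15, avail, exon_room)
        if dmax < 3:
            return None
        d = int(rng.integers(3, dmax + 1))
        if donor_side:
            alt = build.cds[: pos - d] + build.cds[pos:]
            novel = (gs - d, ge) if strand == "+" else (gs, ge + d)
        else:
            alt = build.cds[:pos] + build.cds[pos + d :]
            novel = (gs, ge + d) if strand == "+" else (gs - d, ge)
    return (novel,), (gs, ge), d, alt


def plant_events(reference: SimulatedReference, config: SimulationConfig) -> GroundTruth:
    """Draw planted events per the type rates and conservation design."""
    rng = np.random.default_rng(config.seed + 10_007)
    species = config.species_ids
    n_events = round(config.as_gene_fraction * config.n_genes)

    types = list(config.event_type_rates)
    type_p = np.array([config.event_type_rates[t] for t in types], dtype=float)
    if type_p.sum() <= 0:
        raise SimulationError("event type rates sum to zero")
    type_p = type_p / type_p.sum()

    ks = sorted(config.conservation_design)
    k_counts = {k: int(round(config.conservation_design[k] * n_events)) for k in ks}
    # remainder (rounding drift) goes to private events
    drift = n_events - sum(k_counts.values())
    k_counts[ks[0]] = max(0, k_counts.get(ks[0], 0) + drift)

    k_pool: list[int] = []
    for k in ks:
        k_pool.extend([k] * k_counts[k])
    rng.shuffle(k_pool)
    k_pool = k_pool[:n_events]

    gene_ids = sorted(reference.builds)
    rng.shuffle(gene_ids)
    free = list(gene_ids)

    events: list[PlantedEvent] = []
    for k in k_pool:
        etype = str(rng.choice(types, p=type_p))
        planted = None
        for attempt in range(60):
            if not free:
                break
            idx = int(rng.integers(0, len(free)))
            gene_id = free[idx]
            planted = _plant_one(reference.builds[gene_id], etype, rng)
            if planted is not None:
                free.pop(idx)
                break
            if attempt == 59:
                raise SimulationError(f"could not place a {etype} event after 60 retries")
        if planted is None:
            continue
        intervals, ref_junction, length, alt_cds = planted
        build = reference.builds[gene_id]
        subset = frozenset(
            str(s) for s in rng.choice(species, size=min(k, len(species)), replace=False)
        )
        delta, frameshift, ptc, ptc_pos = _intended_consequence(alt_cds, build.cds)
        events.append(
            PlantedEvent(
                gene_id=gene_id,
                contig_id=build.contig_id,
                event_type=etype,
                intervals=intervals,
                ref_junction=ref_junction,
                event_length=length,
                region="CDS",
                species_set=subset,
                delta_len=delta,
                frameshift=frameshift,
                ptc=ptc,
                ptc_position=ptc_pos,
                alt_cds=alt_cds,
            )
        )
    events.sort(key=lambda e: (e.gene_id, e.event_type, e.intervals))
    return GroundTruth(events=events, config=config)


# ---------------------------------------------------------------------------
# read emission


class _Tally:
    """Planned-evidence bookkeeping mirroring the downstream table schema."""

    def __init__(self, annotation: Annotation, min_gap: int) -> None:
        self.annotation = annotation
        self.min_gap = min_gap
        self.junc: dict[tuple[str, int, int], dict] = {}
        self.cov_bases: dict[tuple[str, int], set[int]] = {}
        self.cov_reads: dict[tuple[str, int], int] = {}
        self.exon_counts: dict[str, int] = {g: 0 for g in annotation.genes}
        self.total = 0
        self._introns = {g.gene_id: g.introns for g in annotation.genes.values()}

    def add(self, contig: str, blocks: list[tuple[int, int]]) -> None:
        self.total += 1
        start = blocks[0][0]
        for i in range(len(blocks) - 1):
            gs, ge = blocks[i][1] + 1, blocks[i + 1][0] - 1
            if ge - gs + 1 < self.min_gap:
                continue
            rec = self.junc.setdefault(
                (contig, gs, ge),
                {"support": 0, "overhang": None, "positions": set(), "unique": 0},
            )
            rec["support"] += 1
            flank = min(blocks[i][1] - blocks[i][0] + 1, blocks[i + 1][1] - blocks[i + 1][0] + 1)
            rec["overhang"] = flank if rec["overhang"] is None else min(rec["overhang"], flank)
            rec["positions"].add(start)
            rec["unique"] += 1
        span_lo, span_hi = blocks[0][0], blocks[-1][1]
        for gene in self.annotation.genes_overlapping(contig, span_lo, span_hi):
            for idx, intr in enumerate(self._introns[gene.gene_id]):
                touched = False
                for bs, be in blocks:
                    lo, hi = max(bs, intr.start), min(be, intr.end)
                    if lo <= hi:
                        touched = True
                        self.cov_bases.setdefault((gene.gene_id, idx), set()).update(
                            range(lo, hi + 1)
                        )
                if touched:
                    key = (gene.gene_id, idx)
                    self.cov_reads[key] = self.cov_reads.get(key, 0) + 1
            if any(
                max(bs, exon.start) <= min(be, exon.end)
                for bs, be in blocks
                for exon in gene.exons
            ):
                self.exon_counts[gene.gene_id] += 1

    def tables(self, species_id: str) -> EvidenceTables:
        junctions = [
            JunctionEvidence(
                contig_id=c, intron_start=gs, intron_end=ge,
                support_reads=rec["support"], min_overhang=rec["overhang"],
                distinct_positions=len(rec["positions"]), unique_support=rec["unique"],
            )
            for (c, gs, ge), rec in sorted(self.junc.items())
        ]
        coverage = []
        for gene_id in sorted(self.annotation.genes):
            for idx, intr in enumerate(self._introns[gene_id]):
                coverage.append(
                    IntronCoverage(
                        gene_id=gene_id, intron_index=idx, intron=intr,
                        covered_bases=len(self.cov_bases.get((gene_id, idx), ())),
                        intron_reads=self.cov_reads.get((gene_id, idx), 0),
                    )
                )
        library = LibraryStats(species_id, self.total, self.total)
        return EvidenceTables(junctions, coverage, self.exon_counts, library)


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            parts.append(f"{s - blocks[i - 1][1] - 1}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


class _SpeciesEmitter:
    def __init__(self, reference: SimulatedReference, config: SimulationConfig,
                 species_id: str) -> None:
        self.reference = reference
        self.config = config
        self.species_id = species_id
        self.records: list[str] = []
        self.tally = _Tally(reference.annotation, config.min_gap)
        self._n = 0

    def emit(self, contig: str, blocks: list[tuple[int, int]]) -> None:
        seq = "".join(
            self.reference.annotation.sequence(contig, s, e) for s, e in blocks
        )
        self._n += 1
        self.records.append(
            "\t".join(
                [
                    f"{self.species_id}.r{self._n}",
                    "0",
                    contig,
                    str(blocks[0][0]),
                    "60",
                    _cigar(blocks),
                    "*", "0", "0",
                    seq,
                    "*",
                ]
            )
        )
        self.tally.add(contig, blocks)

    def write_sam(self, path) -> None:
        with open(path, "w") as out:
            out.write("@HD\tVN:1.6\tSO:coordinate\n")
            for contig in sorted(self.reference.annotation.contigs):
                ln = len(self.reference.annotation.contigs[contig])
                out.write(f"@SQ\tSN:{contig}\tLN:{ln}\n")
            # SAM wants coordinate order when SO:coordinate is declared
            def sort_key(rec: str):
                cols = rec.split("\t")
                return (cols[2], int(cols[3]))
            for rec in sorted(self.records, key=sort_key):
                out.write(rec + "\n")


def _junction_reads(emitter: _SpeciesEmitter, contig: str, ns: int, ne: int,
                    left_lo: int, right_hi: int, support: int) -> None:
    """Spliced reads over a gap [ns..ne]; distinct starts, overhang >= 10."""
    for i in range(support):
        left = min(10 + 2 * i, ns - left_lo)
        right = min(20, right_hi - ne)
        blocks = [(ns - left, ns - 1), (ne + 1, ne + right)]
        emitter.emit(contig, blocks)


def emit_reads(
    reference: SimulatedReference, truth: GroundTruth, config: SimulationConfig
) -> dict[str, _SpeciesEmitter]:
    """Build per-species read sets realizing the planted design.

    Every planted junction receives ``junction_support`` spliced reads with
    >= 10 bp overhangs and distinct start coordinates; planted retained
    introns are tiled to full breadth; every gene gets exonic expression
    reads; optional noise junctions are designed to fail the reliability
    filters (support 1, or 4-5 bp overhangs).
    """
    annotation = reference.annotation
    rng = np.random.default_rng(config.seed + 20_011)
    emitters = {s: _SpeciesEmitter(reference, config, s) for s in config.species_ids}

    events_by_gene: dict[str, PlantedEvent] = {e.gene_id: e for e in truth.events}
    event_introns: set[tuple[str, int, int]] = set()
    for e in truth.events:
        if e.ref_junction is not None:
            event_introns.add((e.gene_id, *e.ref_junction))
        elif e.event_type == IR:
            event_introns.add((e.gene_id, *e.intervals[0]))

    rl = config.read_length
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        exons = gene.exons  # genomic order
        introns = sorted(gene.introns, key=lambda i: i.start)
        left_exon = {i.start: e for i, e in zip(introns, exons)}
        right_exon = {i.end: e for i, e in zip(introns, exons[1:])}
        event = events_by_gene.get(gene_id)

        for emitter in emitters.values():
            # exonic expression reads (first exon, distinct starts)
            ex = exons[0]
            for j in range(config.expression_reads_per_gene):
                s = min(ex.start + 7 * j, ex.end)
                emitter.emit(gene.contig_id, [(s, min(ex.end, s + rl - 1))])
            # constitutive junction reads for every annotated intron
            for intr in introns:
                _junction_reads(
                    emitter, gene.contig_id, intr.start, intr.end,
                    left_exon[intr.start].start, right_exon[intr.end].end, 3,
                )

        if event is None:
            continue
        for species_id in sorted(event.species_set):
            emitter = emitters[species_id]
            if event.event_type == IR:
                gs, ge = event.intervals[0]
                lo = max(left_exon[gs].start, gs - 10)
                hi = min(right_exon[ge].end, ge + 10)
                step = max(rl - 15, 10)
                starts = list(range(lo, max(lo, hi - rl + 1) + 1, step))
                last = max(lo, hi - rl + 1)
                if starts[-1] != last:
                    starts.append(last)
                while len(starts) < 3:
                    starts.append(min(starts[-1] + 3, last) if last > lo else lo)
                for s in starts:
                    emitter.emit(gene.contig_id, [(s, min(s + rl - 1, hi))])
            elif event.event_type == ES:
                ss = event.intervals[0][0]
                se = event.intervals[-1][1]
                k_lo = next(i for i, e in enumerate(exons) if e.start == ss)
                k_hi = next(i for i, e in enumerate(exons) if e.end == se)
                ns, ne = exons[k_lo - 1].end + 1, exons[k_hi + 1].start - 1
                _junction_reads(
                    emitter, gene.contig_id, ns, ne,
                    exons[k_lo - 1].start, exons[k_hi + 1].end,
                    config.junction_support,
                )
            else:  # AltD / AltA / AltP
                ns, ne = event.intervals[0]
                gs, ge = event.ref_junction
                _junction_reads(
                    emitter, gene.contig_id, ns, ne,
                    left_exon[gs].start, right_exon[ge].end,
                    config.junction_support,
                )

    # noise junctions: designed to fail the reliability filters
    n_noise = round(config.noise_junction_rate * max(1, len(truth.events)))
    if n_noise > 0:
        candidates = [
            (g.gene_id, i.start, i.end)
            for g in (annotation.genes[gid] for gid in sorted(annotation.genes))
            for i in g.introns
            if (g.gene_id, i.start, i.end) not in event_introns
        ]
        for species_id in config.species_ids:
            emitter = emitters[species_id]
            if not candidates:
                break
            picks = rng.choice(len(candidates), size=min(n_noise, len(candidates)),
                               replace=False)
            for idx_i, ci in enumerate(sorted(int(p) for p in picks)):
                gene_id, gs, ge = candidates[ci]
                contig = annotation.genes[gene_id].contig_id
                ns, ne = gs + 5, ge - 5
                emitter.emit(contig, [(ns - 5, ns - 1), (ne + 1, ne + 5)])
                if idx_i % 2 == 1:  # support 2 but short overhang
                    emitter.emit(contig, [(ns - 4, ns - 1), (ne + 1, ne + 5)])

    return emitters


@dataclass
class SimulatedDataset:
    reference: SimulatedReference
    truth: GroundTruth
    tables: dict[str, EvidenceTables]
    paths: dict[str, object]

    @property
    def config(self) -> SimulationConfig:
        return self.truth.config


def simulate_dataset(config: SimulationConfig, outdir=None) -> SimulatedDataset:
    """One-call simulation: reference + planted truth + per-species evidence.

    With ``outdir`` set, writes ref.fa / ref.gff3 / <species>.sam, the
    evidence TSVs, the truth tables and a YAML echo of the configuration.
    """
    reference = simulate_reference(config)
    truth = plant_events(reference, config)
    emitters = emit_reads(reference, truth, config)
    tables = {s: em.tally.tables(s) for s, em in emitters.items()}

    paths: dict[str, object] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(reference.annotation.contigs, outdir / "ref.fa")
        write_gff3(reference.annotation, outdir / "ref.gff3")
        paths["fasta"] = outdir / "ref.fa"
        paths["gff3"] = outdir / "ref.gff3"
        paths["sam"] = {}
        for species_id, emitter in emitters.items():
            sam = outdir / f"{species_id}.sam"
            emitter.write_sam(sam)
            paths["sam"][species_id] = sam
            write_evidence_tables(
                tables[species_id],
                outdir / f"{species_id}.junctions.tsv",
                outdir / f"{species_id}.intron_coverage.tsv",
                outdir / f"{species_id}.library.tsv",
                outdir / f"{species_id}.exon_counts.tsv",
            )
        truth_events_table(truth).to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        truth_consequences_table(truth).to_csv(
            outdir / "truth_consequences.tsv", sep="\t", index=False
        )
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_echo(config), fh, sort_keys=True)
    return SimulatedDataset(reference=reference, truth=truth, tables=tables, paths=paths)


def _config_echo(config: SimulationConfig) -> dict:
    echo = asdict(config)
    echo["event_type_rates"] = {str(k): float(v) for k, v in echo["event_type_rates"].items()}
    echo["conservation_design"] = {
        int(k): float(v) for k, v in echo["conservation_design"].items()
    }
    for key in ("exon_count_range", "exon_length_range", "intron_length_range",
                "utr5_range", "utr3_range"):
        echo[key] = list(echo[key])
    return echo


def truth_events_table(truth: GroundTruth):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "contig_id": e.contig_id,
                "event_type": e.event_type,
                "intervals": ";".join(f"{s}-{t}" for s, t in e.intervals),
                "ref_junction": f"{e.ref_junction[0]}-{e.ref_junction[1]}" if e.ref_junction else "",
                "event_length": e.event_length,
                "region": e.region,
                "species": ",".join(sorted(e.species_set)),
            }
            for e in truth.events
        ]
    )


def truth_consequences_table(truth: GroundTruth):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "event_type": e.event_type,
                "delta_len": e.delta_len,
                "frameshift": e.frameshift,
                "ptc": e.ptc,
                "ptc_position": e.ptc_position if e.ptc_position is not None else -1,
            }
            for e in truth.events
        ]
    )
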