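# Methods

## Model and procedure

The pipeline treats alternative splicing as a presence/absence call per
gene, species and event type, made against a single reference annotation
that all species' reads are aligned to. It consumes spliced alignments
(SAM/BAM, gaps as `N` CIGAR operations) or pre-reduced evidence tables,
never raw reads: read alignment is upstream and out of scope, as is any
isoform quantification (no PSI).

Stages, each a module with a TSV interface:

1. **annotation_model** — FASTA + GFF3 → validated gene models. Genes
   with several mRNAs are reduced to the longest model (sum of exon
   lengths; ties broken by lexicographically smallest model id so output
   is deterministic). Introns are the gaps between consecutive exons;
   donor and acceptor are assigned by strand. All public coordinates are
   GFF3-native 1-based inclusive.
2. **alignment_evidence** — per-library junction support (support reads,
   minimum flanking-block length, distinct start coordinates, uniquely
   aligned support), per-intron coverage (breadth and read count) and
   per-gene exonic read counts. Only primary alignments count; "uniquely
   aligned" means primary with no `NH` tag > 1. Gaps shorter than a
   configurable minimum intron size (default 20 bp) are not junctions.
3. **junction_filter** — support ≥ max(2, ⌈2·T/10⁷⌉) for T totally
   mapped reads, overhang ≥ 8 bp on both sides, and ≥ 2 uniquely aligned
   supporting reads at distinct start positions. Each rejected junction
   carries the first criterion it failed (support → overhang → distinct
   → unique), which makes rejection reasons stable and auditable.
4. **as_caller** — IR requires intron reads ≥ the same scaled threshold
   AND breadth ≥ 0.5 (fraction of intron positions touched by aligned
   blocks). ES fires when a junction's ends coincide with annotated exon
   boundaries two or more exons apart; a multi-exon skip is one event.
   Junctions matching no annotated intron exactly are compared to the
   annotated intron with maximal reciprocal overlap (ties: smaller total
   shift, then genomic order): donor shifted → AltD, acceptor → AltA,
   both → AltP.
5. **expression_correlation** — RPKM = reads × 10⁹ / (exonic length ×
   total mapped), longest model, unique reads only; trends are per-bin
   event proportions over feature deciles with an OLS slope t-test.
6. **ecas_matcher** — signature = (gene, type, coordinates, reference
   intron); conservation = same signature in ≥ 2 species.
7. **consequence_caller** — eligibility (single event, in CDS, start
   codon intact), alternative-CDS reconstruction from the genome, PTC and
   frameshift calls.
8. **stats_compare** — G-test and Wilcoxon rank-sum wrappers plus the
   length/position summary tables.
9. **synthetic_data** — the simulation engine described below.

## Key parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `min_support_per_10M` | 2 | reads | junction support floor per 10 M mapped |
| `min_overhang` | 8 | bp | flank required on both sides of a junction |
| `min_distinct_nonrepetitive` | 2 | reads | unique reads at distinct starts |
| `min_ir_breadth` | 0.5 | fraction | intron positions covered for an IR call |
| min gap | 20 | bp | smallest alignment gap treated as a junction |
| ECAS tolerance | 0 | bp | slack on Alt boundary equality |
| trend bins | 10 | — | feature quantile bins |

The support threshold scales with the ceiling and never drops below the
absolute minimum, so shallow libraries are not filtered more loosely than
deep ones; the rule is monotone in library size (property-tested).

## Interpretation choices made where the procedure was genuinely open

* **"Non-repetitive match position"** is read strictly: supporting reads
  must be uniquely aligned *and* start at distinct coordinates, both with
  threshold 2. Both sub-criteria are separately configurable.
* **AltD/AltA orientation** follows the standard convention — AltD means
  the donor (5′ splice site) varies with the acceptor fixed. The
  transposed labeling is available via `swap_alt_labels` because the
  opposite phrasing also circulates.
* **0.5× intron coverage** is breadth (positions touched), not mean
  depth: breadth is robust to single-position pileups; a mean-depth mode
  flag exists.
* **Sharing denominator** is the union of the two species' event sets,
  shared/(|A|+|B|−shared); shares are printed truncated (not rounded) to
  two decimals, the convention the reported percentages follow.
* **PTC definition**: any in-frame stop strictly upstream of the codon
  aligned to the constitutive stop; under a frameshift the annotated stop
  is never in frame, so any in-frame stop counts. No 50-nt NMD rule is
  applied by default (an optional flag implements it for exploration).
* **Orthology** is gene-id identity — valid only because every species is
  mapped to the same reference; no cross-genome homology search is done.
* **Genic-region labels**: an interval whose ends fall in the 5′UTR and
  3′UTR (spanning the entire CDS) gets the 5UTR-CDS label, the first
  transition met in transcription direction, keeping the classifier total.
* **Junction context** is classified from the two exonic bases flanking
  the gap; when several genes contain a junction the smallest gene id
  wins, for deterministic output.
* Canonical GT–AG dinucleotides are *not* enforced on observed junctions
  (an optional flag could be added at the filter); the synthetic genomes
  do emit GT..AG introns.

## The synthetic study

`SimulationConfig` defaults describe the emulated study: four species,
200 genes of 2–7 exons (exons 60–180 bp, introns 60–150 bp, UTRs
15–40 bp), one planted event in half the genes, type mix IR 68% /
AltA 13% / AltP 10% / AltD 5% / ES 4% (IR-dominated, as in plant roots),
and a conservation design planting 55/20/15/10% of events in exactly
1/2/3/4 species. Reads are 75 bp; every planted junction gets 4 spliced
reads with ≥ 10 bp overhangs and distinct starts; planted introns are
tiled to full breadth; every annotated intron also receives constitutive
junction reads, and every gene gets exonic expression reads. Optional
noise junctions are constructed to fail the filters (support 1, or
4–5 bp overhangs) and are placed only on introns hosting no planted
event, so they cannot push a true intron over the IR breadth threshold.

What the generator does **not** model: sequencing errors and base
qualities, multi-mapping reads, expression heterogeneity between genes,
intergenic transcription, non-coding genes, annotation errors, and real
inter-species sequence divergence (all species' reads match the reference
exactly). Passing the planted-recovery suite therefore demonstrates that
the calling logic is a correct function of alignment evidence — not that
the thresholds are well-calibrated for noisy real libraries.

The generator carries its own translation oracle (a hand-written standard
codon table and CDS editor in transcript space), deliberately disjoint
from the consequence caller's genome-space reconstruction via Biopython,
so PTC/frameshift labels are checked across two independent code paths.

## Numerical and degenerate-input choices

* Exact Wilcoxon (min(n, m) ≤ 8) enumerates all C(n+m, n) assignments
  with average ranks for ties; two-sided p = min(1, 2·min(P≤, P≥)).
  The large-sample mode uses a tie-corrected variance and a 0.5
  continuity correction.
* G-test cells with O = 0 contribute 0; Williams' correction is off by
  default (the plain likelihood-ratio G is the canonical definition).
* Degenerate statistics propagate as NA cells (e.g. a length class with
  one observation), never as exceptions from the summary tables.
* A junction exactly matching an annotated intron is constitutive and
  yields no event; single-exon genes yield an empty intron list, not an
  error; genes without CDS features are kept for AS calling but excluded
  from consequence analysis.
* Byte-reproducibility: all randomness flows through a single seed, and
  every output table embeds the tool version, stage and a config hash
  (the output path is excluded from the hash so runs in different
  directories compare equal).

## Problem sizes used by the checks

The test suite and the acceptance script run the simulation at 40–200
genes and four species (about 700–3,500 alignment records per species),
the PTC oracle comparison at ≥ 500 planted genes, the filter property
suite at ≥ 1,000 random junctions, and the null calibrations at 2,000
replicates — sizes chosen so the whole analysis re-runs from scratch in
seconds while every planted quantity is still exactly recoverable.

## Known limitations

* ERANGE-style multiread rescue for RPKM is not implemented; counts use
  unique primary alignments only.
* Identity cutoffs applied at alignment time (e.g. per-species BLAT
  thresholds) cannot be enforced on consumed SAM; they are a property of
  the upstream aligner.
* Multi-exon skips count as one ES event; AltP length is the sum of both
  end shifts.
* No protein-domain comparison and no GO enrichment: both need external
  databases and sit behind documented adapter points (the consequence
  table and the ECAS gene list).
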