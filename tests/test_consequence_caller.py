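"""Alternative-CDS reconstruction and PTC/frameshift calling."""

import numpy as np
import pytest

from ecas_splice.annotation_model import Annotation, ExonInterval, GeneModel
from ecas_splice.as_caller import ALTA, ASEvent, ES, IR
from ecas_splice.consequence_caller import (
    ConsequenceCall,
    ECAS_CLASS,
    NON_ECAS_CLASS,
    build_alt_cds,
    call_consequence,
    check_eligibility,
    consequence_tables,
    constitutive_cds,
)
from ecas_splice.synthetic_data import revcomp, translate


def _gene_from_seq(contig_seq, exons, cds, strand="+", gene_id="g1"):
    gene = GeneModel(
        gene_id=gene_id,
        contig_id="c1",
        strand=strand,
        exons=[ExonInterval("c1", s, e) for s, e in exons],
        cds_start=cds[0],
        cds_end=cds[1],
    )
    return gene, Annotation(genes={gene_id: gene}, contigs={"c1": contig_seq})


# ATGGGG | GTATAAAAG | CCCTAA: 6 bp exon, 9 bp intron, 6 bp exon
PLUS_SEQ = "ATGGGG" + "GTATAAAAG" + "CCCTAA"


class TestEligibility:
    def _events(self, n):
        return [
            ASEvent("sp", "g1", IR, ((101 + i, 200 + i),), 100, "CDS")
            for i in range(n)
        ]

    def test_two_events_ineligible(self, three_exon_gene):
        check = check_eligibility(three_exon_gene, self._events(2))
        assert not check.single_event and not check.eligible

    def test_event_outside_cds_ineligible(self, three_exon_gene):
        event = ASEvent("sp", "g1", IR, ((101, 200),), 100, "3UTR")
        check = check_eligibility(three_exon_gene, [event])
        assert not check.in_cds and not check.eligible

    def test_event_over_start_codon_ineligible(self, three_exon_gene):
        # cds_start=10: an interval covering 10..12 hits the start codon
        event = ASEvent("sp", "g1", IR, ((8, 40),), 33, "CDS")
        check = check_eligibility(three_exon_gene, [event])
        assert not check.start_codon_intact and not check.eligible

    def test_clean_single_cds_event_eligible(self, three_exon_gene):
        check = check_eligibility(three_exon_gene, self._events(1))
        assert check.eligible


class TestBuildAltCds:
    def test_intron_retention_concatenates(self):
        gene, ann = _gene_from_seq(PLUS_SEQ, [(1, 6), (16, 21)], (1, 21))
        event = ASEvent("sp", "g1", IR, ((7, 15),), 9, "CDS")
        assert constitutive_cds(gene, ann) == "ATGGGGCCCTAA"
        assert build_alt_cds(gene, event, ann) == "ATGGGGGTATAAAAGCCCTAA"

    def test_minus_strand_mirror_gives_same_protein(self):
        seq = revcomp(PLUS_SEQ)
        # mirrored coordinates in a 21 bp contig: exon [1..6]->[16..21] etc.
        gene, ann = _gene_from_seq(seq, [(1, 6), (16, 21)], (1, 21), strand="-")
        event = ASEvent("sp", "g1", IR, ((7, 15),), 9, "CDS")
        alt = build_alt_cds(gene, event, ann)
        assert alt == "ATGGGGGTATAAAAGCCCTAA"
        assert translate(alt) == translate("ATGGGGGTATAAAAGCCCTAA")

    def test_exon_skip_removes_sequence(self):
        # exons 6 + 6 + 6, introns 9 + 9
        seq = "ATGGGG" + "GTAAAAAAG" + "CCCGCC" + "GTTTTTTAG" + "GACTAA"
        gene, ann = _gene_from_seq(seq, [(1, 6), (16, 21), (31, 36)], (1, 36))
        event = ASEvent("sp", "g1", ES, ((16, 21),), 6, "CDS")
        alt = build_alt_cds(gene, event, ann)
        assert alt == "ATGGGGGACTAA"
        assert len(alt) - len(constitutive_cds(gene, ann)) == -6

    def test_alt_acceptor_shift_inserts_intron_tail(self):
        gene, ann = _gene_from_seq(PLUS_SEQ, [(1, 6), (16, 21)], (1, 21))
        # acceptor shifted 3 bases into the intron: retains AAG
        event = ASEvent("sp", "g1", ALTA, ((7, 12),), 3, "CDS", ref_junction=(7, 15))
        assert build_alt_cds(gene, event, ann) == "ATGGGG" + "AAG" + "CCCTAA"

    def test_event_outside_gene_is_error(self):
        gene, ann = _gene_from_seq(PLUS_SEQ + "A" * 50, [(1, 6), (16, 21)], (1, 21))
        event = ASEvent("sp", "g1", IR, ((40, 60),), 21, "CDS")
        with pytest.raises(ValueError, match="outside gene span"):
            build_alt_cds(gene, event, ann)


class TestCallConsequence:
    def test_retained_intron_with_inframe_stop_is_ptc(self):
        call = call_consequence("ATGGGGGTATAAAAGCCCTAA", "ATGGGGCCCTAA")
        assert call.ptc and call.ptc_position == 4
        assert not call.frameshift and call.delta_len == 9

    def test_non_triplet_insertion_is_frameshift(self):
        alt = "ATG" + "GTTTTTTTTTTTTTTTG" + "GGGCCCTAA"  # 17 bp insertion
        call = call_consequence(alt, "ATGGGGCCCTAA")
        assert call.frameshift
        assert abs(call.delta_len) % 3 == 2

    def test_identity_has_no_consequence(self):
        call = call_consequence("ATGGGGCCCTAA", "ATGGGGCCCTAA")
        assert not call.ptc and not call.frameshift and call.delta_len == 0

    def test_non_atg_start_is_error(self):
        with pytest.raises(ValueError, match="ATG"):
            call_consequence("TTGGGGTAA", "ATGGGGTAA")

    def test_frameshift_is_pure_function_of_delta(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ins = int(rng.integers(0, 30))
            alt = "ATG" + "GGC" * 5 + "A" * ins + "TAA"
            call = call_consequence(alt, "ATG" + "GGC" * 5 + "TAA")
            assert call.frameshift == (ins % 3 != 0)

    def test_inframe_stopless_insertion_never_ptc(self):
        rng = np.random.default_rng(1)
        stopless = [c for c in ("GGG", "GCA", "TGC", "AAA", "CCT", "TCA") ]
        for _ in range(200):
            ins = "".join(rng.choice(stopless) for _ in range(int(rng.integers(1, 8))))
            alt = "ATG" + ins + "GGGCCCTAA"
            call = call_consequence(alt, "ATGGGGCCCTAA")
            assert not call.ptc, ins


class TestConsequenceTables:
    def _calls(self, etype, n_flag, n_noflag, flag):
        out = []
        for _ in range(n_flag):
            out.append(
                ConsequenceCall("g", etype, 9 if flag == "ptc" else 10,
                                flag == "frameshift", flag == "ptc",
                                1 if flag == "ptc" else None)
            )
        for _ in range(n_noflag):
            out.append(ConsequenceCall("g", etype, 9, False, False, None))
        return out

    def test_percentages_from_counts(self):
        labeled = [(c, ECAS_CLASS) for c in self._calls(IR, 146, 33, "ptc")]
        ptc_table, _ = consequence_tables(labeled)
        row = ptc_table[(ptc_table["class"] == ECAS_CLASS) & (ptc_table.event_type == IR)]
        assert row.pct_yes.iloc[0] == 81.56
        assert row.pct_no.iloc[0] == 18.44

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(2)
        labeled = []
        for etype in (ES, IR, ALTA):
            for cls in (ECAS_CLASS, NON_ECAS_CLASS):
                labeled += [
                    (c, cls)
                    for c in self._calls(etype, int(rng.integers(1, 40)),
                                         int(rng.integers(1, 40)), "ptc")
                ]
        ptc_table, fs_table = consequence_tables(labeled)
        for table in (ptc_table, fs_table):
            nonempty = table[(table.n_yes + table.n_no) > 0]
            assert ((nonempty.pct_yes + nonempty.pct_no) - 100.0).abs().max() <= 0.01

    def test_empty_class_yields_zero_row(self):
        ptc_table, _ = consequence_tables([])
        assert (ptc_table.n_yes == 0).all()
        assert (ptc_table.pct_yes == 0.0).all()


def test_generator_oracle_agreement(small_dataset):
    """Consequence calls must match the generator's independent translation."""
    ann = small_dataset.reference.annotation
    for planted in small_dataset.truth.events:
        gene = ann.genes[planted.gene_id]
        event = planted.as_event("sp1")
        check = check_eligibility(gene, [event])
        assert check.eligible, planted.gene_id
        alt = build_alt_cds(gene, event, ann)
        call = call_consequence(alt, constitutive_cds(gene, ann),
                                planted.gene_id, planted.event_type)
        assert call.delta_len == planted.delta_len
        assert call.frameshift == planted.frameshift
        assert call.ptc == planted.ptc
        assert call.ptc_position == planted.ptc_position
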