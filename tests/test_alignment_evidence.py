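"""SAM evidence extraction and the TSV round trip."""

import pytest

from ecas_splice.alignment_evidence import (
    EvidenceError,
    extract_evidence,
    load_evidence_tables,
    write_evidence_tables,
)
from ecas_splice.as_caller import call_events

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:c1\tLN:600\n"


def _sam(tmp_path, records):
    path = tmp_path / "reads.sam"
    path.write_text(SAM_HEADER + "".join(records))
    return path


def _rec(name, pos, cigar, flag=0, tags=""):
    return f"{name}\t{flag}\tc1\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*{tags}\n"


def test_gap_spanning_reads_yield_junction_support(tmp_path, toy_annotation):
    # three reads spanning the gap [101..200]; flanks 10/12 on the tightest read
    records = [
        _rec("r1", 91, "10M100N12M"),
        _rec("r2", 81, "20M100N30M"),
        _rec("r3", 71, "30M100N40M"),
    ]
    tables = extract_evidence(_sam(tmp_path, records), toy_annotation)
    assert len(tables.junctions) == 1
    j = tables.junctions[0]
    assert (j.intron_start, j.intron_end) == (101, 200)
    assert j.support_reads == 3
    assert j.min_overhang == 10
    assert j.distinct_positions == 3
    assert j.unique_support == 3


def test_read_within_intron_counts_coverage(tmp_path, toy_annotation):
    tables = extract_evidence(_sam(tmp_path, [_rec("r1", 111, "30M")]), toy_annotation)
    cov = {(c.gene_id, c.intron_index): c for c in tables.intron_coverage}
    first = cov[("g1", 0)]
    assert first.covered_bases == 30
    assert first.intron_reads == 1
    assert cov[("g1", 1)].covered_bases == 0


def test_identical_start_positions_collapse_to_one(tmp_path, toy_annotation):
    records = [_rec("r1", 91, "10M100N12M"), _rec("r2", 91, "10M100N12M")]
    tables = extract_evidence(_sam(tmp_path, records), toy_annotation)
    assert tables.junctions[0].support_reads == 2
    assert tables.junctions[0].distinct_positions == 1


def test_secondary_and_multimapped_reads_are_excluded(tmp_path, toy_annotation):
    records = [
        _rec("r1", 91, "10M100N12M"),
        _rec("r1", 91, "10M100N12M", flag=256),  # secondary: skipped entirely
        _rec("r2", 89, "12M100N12M", tags="\tNH:i:3"),  # multimapped: not unique
    ]
    tables = extract_evidence(_sam(tmp_path, records), toy_annotation)
    j = tables.junctions[0]
    assert j.support_reads == 2
    assert j.unique_support == 1
    assert tables.library.total_mapped_reads == 2
    assert tables.library.uniquely_mapped_reads == 1


def test_multi_gap_read_contributes_to_each_junction(tmp_path, toy_annotation):
    tables = extract_evidence(
        _sam(tmp_path, [_rec("r1", 91, "10M100N100M100N20M")]), toy_annotation
    )
    keys = {(j.intron_start, j.intron_end) for j in tables.junctions}
    assert keys == {(101, 200), (301, 400)}


def test_small_gaps_below_minimum_are_not_junctions(tmp_path, toy_annotation):
    tables = extract_evidence(
        _sam(tmp_path, [_rec("r1", 91, "10M10N12M")]), toy_annotation
    )
    assert tables.junctions == []


def test_unmapped_only_file_warns_and_returns_empty(tmp_path, toy_annotation):
    records = [f"r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"]
    with pytest.warns(UserWarning, match="no mapped reads"):
        tables = extract_evidence(_sam(tmp_path, records), toy_annotation)
    assert tables.junctions == []
    assert tables.library.total_mapped_reads == 0


def test_tsv_round_trip_preserves_tables(tmp_path, noisy_dataset_dir):
    outdir, dataset = noisy_dataset_dir
    annotation = dataset.reference.annotation
    tables = dataset.tables["sp1"]
    paths = [tmp_path / n for n in ("j.tsv", "i.tsv", "s.tsv", "e.tsv")]
    write_evidence_tables(tables, *paths)
    loaded = load_evidence_tables(paths[0], paths[1], paths[2], annotation, exon_tsv=paths[3])
    assert [j.__dict__ for j in loaded.junctions] == [j.__dict__ for j in tables.junctions]
    assert [
        (c.gene_id, c.intron_index, c.covered_bases, c.intron_reads)
        for c in loaded.intron_coverage
    ] == [
        (c.gene_id, c.intron_index, c.covered_bases, c.intron_reads)
        for c in tables.intron_coverage
    ]
    assert loaded.exon_counts == tables.exon_counts
    assert loaded.library == tables.library


def test_empty_junction_table_yields_no_junction_events(tmp_path, toy_annotation):
    (tmp_path / "j.tsv").write_text(
        "contig\tintron_start\tintron_end\tsupport\tmin_overhang\t"
        "distinct_positions\tunique_support\n"
    )
    (tmp_path / "i.tsv").write_text("gene_id\tintron_index\tcovered_bases\tintron_reads\n")
    (tmp_path / "s.tsv").write_text("species_id\ttotal_mapped\tuniquely_mapped\nsp1\t1000\t900\n")
    tables = load_evidence_tables(
        tmp_path / "j.tsv", tmp_path / "i.tsv", tmp_path / "s.tsv", toy_annotation
    )
    assert call_events(tables, toy_annotation) == []


def test_inconsistent_library_stats_rejected(tmp_path, toy_annotation):
    (tmp_path / "j.tsv").write_text(
        "contig\tintron_start\tintron_end\tsupport\tmin_overhang\t"
        "distinct_positions\tunique_support\n"
    )
    (tmp_path / "i.tsv").write_text("gene_id\tintron_index\tcovered_bases\tintron_reads\n")
    (tmp_path / "s.tsv").write_text("species_id\ttotal_mapped\tuniquely_mapped\nsp1\t100\t200\n")
    with pytest.raises(EvidenceError):
        load_evidence_tables(
            tmp_path / "j.tsv", tmp_path / "i.tsv", tmp_path / "s.tsv", toy_annotation
        )


def test_missing_column_is_schema_error(tmp_path, toy_annotation):
    (tmp_path / "j.tsv").write_text("contig\tintron_start\tintron_end\n")
    (tmp_path / "i.tsv").write_text("gene_id\tintron_index\tcovered_bases\tintron_reads\n")
    (tmp_path / "s.tsv").write_text("species_id\ttotal_mapped\tuniquely_mapped\nsp1\t10\t10\n")
    with pytest.raises(EvidenceError, match="missing column"):
        load_evidence_tables(
            tmp_path / "j.tsv", tmp_path / "i.tsv", tmp_path / "s.tsv", toy_annotation
        )


def test_junction_support_conserves_gap_count(noisy_dataset_dir):
    """Sum of per-junction support equals the number of emitted gaps."""
    outdir, dataset = noisy_dataset_dir
    annotation = dataset.reference.annotation
    extracted = extract_evidence(outdir / "sp2.sam", annotation, species_id="sp2")
    n_gaps = 0
    with open(outdir / "sp2.sam") as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            n_gaps += line.split("\t")[5].count("N")
    assert sum(j.support_reads for j in extracted.junctions) == n_gaps


def test_extraction_recovers_planted_junction_table(noisy_dataset_dir):
    outdir, dataset = noisy_dataset_dir
    annotation = dataset.reference.annotation
    extracted = extract_evidence(outdir / "sp1.sam", annotation, species_id="sp1")
    planted = dataset.tables["sp1"]
    assert [j.__dict__ for j in extracted.junctions] == [
        j.__dict__ for j in planted.junctions
    ]
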