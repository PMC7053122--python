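"""GFF3/GTF parsing, hierarchy validation, and annotation statistics."""

import gzip

import pytest

from asmqc.annotation_metrics import annotation_metrics
from asmqc.annotation_model import (
    ExonInterval,
    parse_annotation,
    validate_against_assembly,
    write_gff3,
)
from asmqc.errors import AnnotationError
from asmqc.sequence_io import SequenceRecord

from conftest import make_gene

MINIMAL_GFF3 = """##gff-version 3
chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=g1
chr1\tsrc\texon\t100\t200\t.\t+\t.\tParent=t1
"""

MINIMAL_GTF = (
    'chr1\tsrc\tgene\t100\t500\t.\t+\t.\tgene_id "g1";\n'
    'chr1\tsrc\ttranscript\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
)


def write(tmp_path, name, content, compress=False):
    p = tmp_path / name
    if compress:
        with gzip.open(p, "wt") as fh:
            fh.write(content)
    else:
        p.write_text(content)
    return p


class TestParseAnnotation:
    @pytest.mark.parametrize("compress", [False, True])
    def test_minimal_gff3_hierarchy(self, tmp_path, compress):
        genes = parse_annotation(write(tmp_path, "a.gff3", MINIMAL_GFF3, compress))
        (g,) = genes
        assert g.id == "g1" and g.length == 401
        (tx,) = g.transcripts
        assert tx.id == "t1"
        (exon,) = tx.exons
        assert exon.length == 101

    def test_gtf_dialect_equivalent(self, tmp_path):
        g3 = parse_annotation(write(tmp_path, "a.gff3", MINIMAL_GFF3))
        gt = parse_annotation(write(tmp_path, "a.gtf", MINIMAL_GTF))
        assert g3[0].id == gt[0].id
        assert g3[0].transcripts[0].id == gt[0].transcripts[0].id
        assert g3[0].transcripts[0].exons == gt[0].transcripts[0].exons

    def test_multi_parent_exon_in_both_transcripts(self, tmp_path):
        content = MINIMAL_GFF3 + (
            "chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t2;Parent=g1\n"
            "chr1\tsrc\texon\t300\t400\t.\t+\t.\tParent=t1,t2\n"
        )
        (g,) = parse_annotation(write(tmp_path, "m.gff3", content))
        by_id = {tx.id: tx for tx in g.transcripts}
        assert len(by_id["t1"].exons) == 2
        assert ExonInterval("chr1", 300, 400, "+") in by_id["t2"].exons

    def test_children_before_parents_resolved(self, tmp_path):
        shuffled = (
            "chr1\tsrc\texon\t100\t200\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1\n"
        )
        genes = parse_annotation(write(tmp_path, "r.gff3", shuffled))
        assert genes[0].transcripts[0].exons[0].length == 101

    def test_orphan_exon_rejected(self, tmp_path):
        content = MINIMAL_GFF3 + "chr1\tsrc\texon\t300\t400\t.\t+\t.\tParent=t99\n"
        with pytest.raises(AnnotationError, match="orphan.*t99"):
            parse_annotation(write(tmp_path, "o.gff3", content))

    @pytest.mark.parametrize(
        "bad_line, match",
        [
            ("chr1\tsrc\texon\t500\t100\t.\t+\t.\tParent=t1", ":5.*malformed interval"),
            ("chr1\tsrc\texon\tabc\t600\t.\t+\t.\tParent=t1", ":5"),
        ],
    )
    def test_bad_coordinates_report_line_number(self, tmp_path, bad_line, match):
        content = MINIMAL_GFF3 + bad_line + "\n"
        with pytest.raises(AnnotationError, match=match):
            parse_annotation(write(tmp_path, "b.gff3", content))

    def test_exonless_transcript_gets_declared_span(self, tmp_path):
        content = (
            "chr1\tsrc\tgene\t10\t90\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t10\t90\t.\t+\t.\tID=t1;Parent=g1\n"
        )
        with pytest.warns(UserWarning, match="no exon features"):
            (g,) = parse_annotation(write(tmp_path, "s.gtf2", content))
        assert g.transcripts[0].exons == [ExonInterval("chr1", 10, 90, "+")]

    def test_overlapping_exons_merged(self, tmp_path):
        content = MINIMAL_GFF3 + "chr1\tsrc\texon\t150\t250\t.\t+\t.\tParent=t1\n"
        with pytest.warns(UserWarning, match="overlapping"):
            (g,) = parse_annotation(write(tmp_path, "ov.gff3", content))
        assert g.transcripts[0].exons == [ExonInterval("chr1", 100, 250, "+")]

    def test_embedded_fasta_ignored(self, tmp_path):
        content = MINIMAL_GFF3 + "##FASTA\n>chr1\nACGT\n"
        with pytest.warns(UserWarning, match="FASTA"):
            genes = parse_annotation(write(tmp_path, "f.gff3", content))
        assert len(genes) == 1

    def test_gff3_round_trip(self, tmp_path):
        genes = parse_annotation(write(tmp_path, "a.gff3", MINIMAL_GFF3))
        out = tmp_path / "rt.gff3"
        write_gff3(genes, out)
        again = parse_annotation(out)
        assert [(g.id, g.seqid, g.start, g.end, g.strand) for g in genes] == [
            (g.id, g.seqid, g.start, g.end, g.strand) for g in again
        ]
        assert genes[0].transcripts[0].exons == again[0].transcripts[0].exons


class TestValidateAgainstAssembly:
    def test_consistent(self):
        genes = [make_gene("g1", "chr1", "+", [(1, 3), (7, 9)])]
        report = validate_against_assembly(genes, [SequenceRecord("chr1", "A" * 20)])
        assert report.ok

    def test_missing_seqid_named_in_report(self):
        genes = [make_gene("g1", "chr9", "+", [(1, 3)])]
        report = validate_against_assembly(genes, [SequenceRecord("chr1", "A" * 20)])
        assert not report.ok
        assert "chr9" in report.missing_seqids
        assert "chr9" in str(report)

    def test_out_of_bounds_feature_reported(self):
        genes = [make_gene("g1", "chr1", "+", [(100, 500)])]
        report = validate_against_assembly(genes, [SequenceRecord("chr1", "A" * 400)])
        assert not report.ok
        assert any("500" in e for e in report.out_of_bounds)


class TestAnnotationMetrics:
    def test_worked_example(self):
        g = make_gene("g1", "chr1", "+", [(100, 200), (250, 300), (400, 500)])
        m = annotation_metrics([g])
        assert m.n_genes == 1 and m.n_transcripts == 1 and m.n_exons == 3
        assert m.mean_gene_length == 401
        assert m.mean_transcript_spliced_length == 101 + 51 + 101 == 253
        assert m.mean_exon_length == pytest.approx(253 / 3)
        assert m.n_monoexonic_transcripts == 0

    def test_uniform_single_exon_genes(self):
        genes = [
            make_gene("g1", "chr1", "+", [(1, 100)]),
            make_gene("g2", "chr1", "-", [(201, 300)]),
        ]
        m = annotation_metrics(genes)
        assert m.mean_exons_per_transcript == 1.0
        assert m.n_monoexonic_transcripts == 2
        assert m.mean_gene_length == m.median_gene_length == 100
        assert m.longest_gene == m.shortest_gene == 100

    def test_shared_exon_counts_per_transcript(self, tmp_path):
        content = (
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t2;Parent=g1\n"
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1,t2\n"
        )
        p = tmp_path / "sh.gff3"
        p.write_text(content)
        m = annotation_metrics(parse_annotation(p))
        assert m.n_exons == 2  # once per transcript
        assert m.mean_transcripts_per_gene == 2.0

    def test_shift_invariance(self):
        base = [make_gene("g1", "chr1", "+", [(100, 200), (400, 500)])]
        shifted = [make_gene("g1", "chr1", "+", [(1100, 1200), (1400, 1500)])]
        m1, m2 = annotation_metrics(base), annotation_metrics(shifted)
        for f in (
            "n_exons",
            "mean_gene_length",
            "mean_transcript_spliced_length",
            "mean_exon_length",
        ):
            assert getattr(m1, f) == getattr(m2, f)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            annotation_metrics([])
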