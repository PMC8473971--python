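import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tepav.annotations import (
    AMBIGUOUS,
    MISSING,
    PRESENT,
    AnnotationError,
    CallMatrix,
    GeneModel,
    TEAnnotation,
    assign_nesting_by_containment,
    merge_intervals,
    read_bed,
    read_gene_models,
    read_homolog_table,
    read_te_annotations,
    write_bed,
    write_homolog_table,
)

TE_GFF = """##gff-version 3
chr1\t.\tLTR_retrotransposon\t1001\t8000\t.\t+\t.\tID=te1;fam=RLG00001;ltr_identity=0.98
chr1\t.\tTIR_transposon\t2000\t3000\t.\t+\t.\tID=te2;fam=DTA00003
chr2\t.\thelitron\t500\t900\t.\t-\t.\tID=te3;fam=DHH00001
"""

GENE_GFF = """##gff-version 3
chr1\t.\tgene\t100\t1000\t.\t+\t.\tID=g1
chr1\t.\tmRNA\t100\t1000\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\t.\texon\t100\t300\t.\t+\t.\tID=g1.e1;Parent=g1.t1
chr1\t.\texon\t600\t1000\t.\t+\t.\tID=g1.e2;Parent=g1.t1
chr1\t.\tfive_prime_UTR\t100\t150\t.\t+\t.\tID=g1.u5;Parent=g1.t1
chr2\t.\tgene\t50\t400\t.\t-\t.\tID=g2
chr2\t.\tmRNA\t50\t400\t.\t-\t.\tID=g2.t1;Parent=g2
chr2\t.\texon\t50\t400\t.\t-\t.\tID=g2.e1;Parent=g2.t1
"""


class TestReadTEAnnotations:
    def test_field_mapping_and_fraction_similarity(self, tmp_path):
        path = tmp_path / "tes.gff3"
        path.write_text(TE_GFF)
        tes = read_te_annotations(path, "B73")
        te1 = next(t for t in tes if t.te_id == "te1")
        assert (te1.chrom, te1.start, te1.end) == ("chr1", 1001, 8000)
        assert te1.order == "LTR"
        assert te1.family == "RLG00001"
        assert te1.ltr_similarity == pytest.approx(98.0)
        assert te1.assembly == "B73"

    def test_non_ltr_has_no_similarity(self, tmp_path):
        path = tmp_path / "tes.gff3"
        path.write_text(TE_GFF)
        tes = {t.te_id: t for t in read_te_annotations(path, "B73")}
        assert tes["te2"].ltr_similarity is None
        assert tes["te3"].order == "Helitron"

    def test_nesting_resolved_by_containment_fallback(self, tmp_path):
        path = tmp_path / "tes.gff3"
        path.write_text(TE_GFF)
        tes = {t.te_id: t for t in read_te_annotations(path, "B73")}
        assert tes["te2"].nested_in == "te1"  # 2000-3000 inside 1001-8000
        assert tes["te1"].nested_in is None

    def test_nesting_attribute_wins_when_present(self, tmp_path):
        gff = TE_GFF.replace("ID=te2;", "ID=te2;nested_in=te1;")
        path = tmp_path / "tes.gff3"
        path.write_text(gff)
        tes = {t.te_id: t for t in read_te_annotations(path, "B73")}
        assert tes["te2"].nested_in == "te1"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr1 only three fields\n")
        with pytest.raises(AnnotationError, match="line 2"):
            read_te_annotations(path, "B73")

    def test_similarity_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "tes.gff3"
        path.write_text(TE_GFF.replace("ltr_identity=0.98", "ltr_identity=140"))
        with pytest.raises(AnnotationError, match="outside"):
            read_te_annotations(path, "B73")


class TestContainmentNesting:
    def _te(self, te_id, start, end, chrom="chr1"):
        return TEAnnotation(te_id, "a", chrom, start, end, "TIR")

    def test_immediate_parent_of_multilevel_nest(self):
        tes = [self._te("A", 1, 10000), self._te("B", 100, 5000), self._te("C", 200, 400)]
        assign_nesting_by_containment(tes)
        parents = {t.te_id: t.nested_in for t in tes}
        assert parents == {"A": None, "B": "A", "C": "B"}

    def test_identical_intervals_are_not_nesting(self):
        tes = [self._te("A", 10, 20), self._te("B", 10, 20)]
        assign_nesting_by_containment(tes)
        assert all(t.nested_in is None for t in tes)

    def test_different_chromosomes_do_not_nest(self):
        tes = [self._te("A", 1, 10000), self._te("B", 100, 200, chrom="chr9")]
        assign_nesting_by_containment(tes)
        assert tes[1].nested_in is None

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60)),
            min_size=2,
            max_size=25,
        )
    )
    def test_every_assigned_parent_contains_its_child(self, spans):
        tes = [
            TEAnnotation(f"t{i}", "a", "chr1", s, s + w, "LTR")
            for i, (s, w) in enumerate(spans)
        ]
        assign_nesting_by_containment(tes)
        by_id = {t.te_id: t for t in tes}
        for te in tes:
            if te.nested_in is not None:
                parent = by_id[te.nested_in]
                assert parent.contains(te)
                assert (parent.start, parent.end) != (te.start, te.end)


class TestGeneModels:
    def test_introns_from_exon_gaps(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GENE_GFF)
        genes = {g.gene_id: g for g in read_gene_models(path)}
        assert genes["g1"].introns == [(301, 599)]
        assert genes["g1"].utr5 == [(100, 150)]
        assert genes["g2"].introns == []

    def test_longest_transcript_defines_structure(self, tmp_path):
        gff = GENE_GFF + (
            "chr1\t.\tmRNA\t100\t1000\t.\t+\t.\tID=g1.t2;Parent=g1\n"
            "chr1\t.\texon\t100\t200\t.\t+\t.\tID=g1.t2e;Parent=g1.t2\n"
        )
        path = tmp_path / "genes.gff3"
        path.write_text(gff)
        genes = {g.gene_id: g for g in read_gene_models(path)}
        # t1 spliced length 201+401 beats t2's 101
        assert genes["g1"].exons == [(100, 300), (600, 1000)]

    def test_exon_outside_gene_bounds_rejected(self):
        with pytest.raises(AnnotationError, match="outside gene bounds"):
            GeneModel("g", "chr1", 100, 1000, "+", exons=[(50, 300)])


class TestHomologTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "hom.tsv"
        header = "nonredundant_id\tassembly\tte_id\tsource_assembly\n"
        path.write_text(header + "".join("\t".join(r) + "\n" for r in rows))
        return path

    def test_groups_assembled(self, tmp_path):
        path = self._write(
            tmp_path,
            [("nr1", "B73", "teA", "B73"), ("nr1", "Mo17", "teB", "B73"),
             ("nr2", "B73", "teC", "B73")],
        )
        groups = {g.nonredundant_id: g for g in read_homolog_table(path)}
        assert groups["nr1"].members == [("B73", "teA"), ("Mo17", "teB")]
        assert len(groups["nr2"].members) == 1

    def test_duplicate_membership_rejected(self, tmp_path):
        path = self._write(
            tmp_path, [("nr1", "B73", "teA", "B73"), ("nr2", "B73", "teA", "B73")]
        )
        with pytest.raises(AnnotationError, match="claimed by groups"):
            read_homolog_table(path)

    def test_round_trip(self, tmp_path):
        path = self._write(
            tmp_path, [("nr1", "B73", "teA", "B73"), ("nr1", "W22", "teB", "B73")]
        )
        groups = read_homolog_table(path)
        out = tmp_path / "out.tsv"
        write_homolog_table(groups, out)
        assert read_homolog_table(out) == groups


class TestCallMatrix:
    def _matrix(self):
        labels = pd.DataFrame(
            [[PRESENT, AMBIGUOUS, MISSING], ["absent", PRESENT, PRESENT]],
            index=pd.Index(["te1", "te2"], name="te_id"),
            columns=["s1", "s2", "s3"],
        )
        probs = pd.DataFrame(
            [[0.93, 0.55, np.nan], [0.01, 0.99, 0.71]],
            index=labels.index,
            columns=labels.columns,
        )
        return CallMatrix(labels, probs)

    def test_round_trip(self, tmp_path):
        m = self._matrix()
        path = tmp_path / "calls.tsv"
        m.write(path)
        assert CallMatrix.read(path) == m

    def test_probability_token_parsed(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("te_id\ts1\nte1\tambiguous,0.55\n")
        m = CallMatrix.read(path)
        assert m.labels.loc["te1", "s1"] == AMBIGUOUS
        assert m.probabilities.loc["te1", "s1"] == 0.55

    def test_na_token_is_missing(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("te_id\ts1\nte1\tNA\n")
        assert CallMatrix.read(path).labels.loc["te1", "s1"] == MISSING

    def test_unknown_token_rejected(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("te_id\ts1\nte1\tmaybe\n")
        with pytest.raises(AnnotationError, match="unknown call label"):
            CallMatrix.read(path)

    def test_threshold_consistency_check(self):
        m = self._matrix()
        m.check_thresholds()  # labels match probabilities
        bad = CallMatrix(
            m.labels.replace(AMBIGUOUS, PRESENT), m.probabilities
        )
        with pytest.raises(AnnotationError, match="inconsistent"):
            bad.check_thresholds()

    @given(
        st.integers(1, 5),
        st.integers(2, 4),
        st.data(),
    )
    def test_label_round_trip_property(self, n_rows, n_cols, data):
        import tempfile
        from pathlib import Path

        cells = data.draw(
            st.lists(
                st.lists(
                    st.sampled_from(["present", "absent", "ambiguous", "missing"]),
                    min_size=n_cols, max_size=n_cols,
                ),
                min_size=n_rows, max_size=n_rows,
            )
        )
        labels = pd.DataFrame(
            cells,
            index=pd.Index([f"te{i}" for i in range(n_rows)], name="te_id"),
            columns=[f"s{j}" for j in range(n_cols)],
        )
        m = CallMatrix(labels)
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "m.tsv"
            m.write(path)
            assert CallMatrix.read(path) == m


class TestBed:
    def test_round_trip_is_one_based_inclusive(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t99\t200\nchr2\t0\t10\n")
        df = read_bed(path)
        assert df.iloc[0].tolist() == ["chr1", 100, 200]
        assert df.iloc[1].tolist() == ["chr2", 1, 10]
        out = tmp_path / "o.bed"
        write_bed(df, out)
        assert out.read_text() == path.read_text()

    def test_merge_intervals(self):
        df = pd.DataFrame(
            {"chrom": ["c", "c", "c"], "start": [1, 5, 20], "end": [10, 12, 30]}
        )
        merged = merge_intervals(df)
        assert merged.values.tolist() == [["c", 1, 12], ["c", 20, 30]]
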