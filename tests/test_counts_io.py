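import numpy as np
import pandas as pd
import pytest

from tnhomeo.counts_io import (CountsIOError, CountMatrix, SampleDesign,
                               build_design_matrix, read_count_table,
                               validate_dataset, write_count_table)
from tnhomeo.simdata import default_design


def test_read_count_table_parses_bedtools_sentinel(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("locus_tag\ts1\ts2\ngA\t0\t.\ngB\t5\t\ngC\t.\t7\n")
    cm = read_count_table(p, "unique")
    assert cm.genes == ["gA", "gB", "gC"]
    np.testing.assert_array_equal(cm.values,
                                  [[0, 0], [5, 0], [0, 7]])


def test_count_table_roundtrip(tmp_path, counts_3x2):
    p = tmp_path / "c.tsv"
    write_count_table(counts_3x2, p)
    back = read_count_table(p, "unique")
    assert back.genes == counts_3x2.genes
    assert back.samples == counts_3x2.samples
    np.testing.assert_array_equal(back.values, counts_3x2.values)


def test_duplicate_locus_tag_is_named(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("locus_tag\ts1\nCCNA_00001\t3\nCCNA_00001\t4\n")
    with pytest.raises(CountsIOError, match="CCNA_00001"):
        read_count_table(p, "total")


def test_non_integer_cell_names_row_and_column(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("locus_tag\ts1\ngA\t3.5\n")
    with pytest.raises(CountsIOError, match="gA.*s1"):
        read_count_table(p, "total")


def test_negative_counts_rejected():
    with pytest.raises(CountsIOError, match="negative"):
        CountMatrix(["g1"], ["s1"], np.array([[-1]]), "unique")


class TestAnnotation:
    def test_read_bed_keeps_half_open_coords(self, tmp_path):
        from tnhomeo.counts_io import read_annotation
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t400\tCCNA_00001\t0\t+\n"
                     "chr1\t500\t900\tCCNA_00002\t0\t-\n")
        ann = read_annotation(p)
        assert ann.locus_tags == ["CCNA_00001", "CCNA_00002"]
        row = ann.table.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (100, 400, "+")

    def test_read_gff3_converts_to_zero_based(self, tmp_path):
        from tnhomeo.counts_io import read_annotation
        p = tmp_path / "genes.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\t.\tgene\t101\t400\t.\t+\t.\t"
                     "ID=g1;locus_tag=CCNA_00001\n")
        ann = read_annotation(p)
        row = ann.table.iloc[0]
        assert (row["start"], row["end"]) == (100, 400)

    def test_invalid_interval_rejected(self):
        from tnhomeo.counts_io import GeneAnnotation
        with pytest.raises(CountsIOError, match="start"):
            GeneAnnotation(pd.DataFrame([
                {"locus_tag": "g1", "chromosome": "c", "start": 10,
                 "end": 10, "strand": "+"}]))


class TestSampleDesign:
    def test_control_with_level_rejected(self):
        rows = pd.DataFrame([{"sample_id": "x", "strain": "wt",
                              "stress": "control", "level": "low",
                              "replicate": 1, "batch": "b1"}])
        with pytest.raises(CountsIOError, match="level"):
            SampleDesign(rows)

    def test_missing_control_names_strain(self, two_group_design):
        stressed = two_group_design.subset(
            two_group_design.table["stress"] != "control")
        with pytest.raises(CountsIOError, match="wt"):
            stressed.require_controls()


class TestDesignMatrix:
    def test_full_coding_column_count_two_strains(self):
        # S strains -> S strain cols + S*3 stress cols + S*9 level cols
        d = default_design(strains=("wt", "dlon"), n_batches=1)
        X = build_design_matrix(d, coding="full")
        S = 2
        assert X.shape[1] == S + S * 3 + S * 9

    def test_control_rows_zero_in_stress_and_level_blocks(self,
                                                          two_group_design):
        X = build_design_matrix(two_group_design, coding="full")
        ctrl = two_group_design.table["stress"] == "control"
        nested = [c for c in X.columns if not c.startswith("g[")]
        assert (X.loc[ctrl.to_numpy(), nested].to_numpy() == 0).all()

    def test_reference_coding_full_rank_with_intercept(self):
        d = default_design(strains=("wt", "dlon"), n_batches=1)
        X = build_design_matrix(d, coding="reference").to_numpy()
        Xc = np.column_stack([np.ones(len(X)), X])
        assert np.linalg.matrix_rank(Xc) == Xc.shape[1]

    def test_row_permutation_permutes_design_rows(self, one_strain_design):
        X = build_design_matrix(one_strain_design, coding="full")
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(one_strain_design.table))
        shuffled = SampleDesign(
            one_strain_design.table.iloc[perm].reset_index(drop=True))
        X2 = build_design_matrix(shuffled, coding="full")
        pd.testing.assert_frame_equal(X2, X.iloc[perm])


class TestValidateDataset:
    def _pair(self):
        genes, samples = ["g1", "g2"], ["a", "b"]
        total = CountMatrix(genes, samples, np.array([[4, 6], [2, 0]]),
                            "total")
        unique = CountMatrix(genes, samples, np.array([[3, 5], [1, 0]]),
                             "unique")
        design = SampleDesign(pd.DataFrame([
            {"sample_id": "a", "strain": "wt", "stress": "control",
             "level": "none", "replicate": 1, "batch": "b1"},
            {"sample_id": "b", "strain": "wt", "stress": "heat",
             "level": "low", "replicate": 1, "batch": "b1"}]))
        return total, unique, design

    def test_consistent_dataset_has_no_issues(self):
        total, unique, design = self._pair()
        assert validate_dataset(total, unique, design) == []

    def test_unique_exceeding_total_names_gene_and_sample(self):
        total, unique, design = self._pair()
        unique.values[0, 1] = 99
        issues = validate_dataset(total, unique, design)
        assert any(i["kind"] == "unique_gt_total" and i["gene"] == "g1"
                   and i["sample"] == "b" for i in issues)

    def test_blank_batch_label_reported(self):
        total, unique, design = self._pair()
        design.table.loc[0, "batch"] = " "
        issues = validate_dataset(total, unique, design)
        assert any("batch" in i["kind"] for i in issues)
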