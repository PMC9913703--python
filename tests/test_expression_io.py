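import numpy as np
import pytest

from osap.expression_io import (
    ExpressionMatrix,
    GeneSignature,
    ParseError,
    collapse_probes,
    quantile_normalize,
    read_expression,
    read_gmt,
    read_sample_table,
    write_expression,
    write_gmt,
)


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

class TestReadWriteExpression:
    def test_tsv_round_trip_values(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1.5\t2.5\ng2\t3.25\t-0.75\n")
        m = read_expression(str(path), format="tsv")
        assert m.gene_ids == ["g1", "g2"]
        assert m.sample_ids == ["s1", "s2"]
        np.testing.assert_allclose(m.values, [[1.5, 2.5], [3.25, -0.75]])

    @pytest.mark.parametrize("fmt", ["gct", "tsv"])
    def test_write_then_read_round_trip(self, tmp_path, random_matrix, fmt):
        path = tmp_path / f"m.{fmt}"
        write_expression(random_matrix, str(path), format=fmt)
        back = read_expression(str(path), format=fmt)
        assert back.gene_ids == random_matrix.gene_ids
        assert back.sample_ids == random_matrix.sample_ids
        np.testing.assert_allclose(back.values, random_matrix.values, atol=1e-12, rtol=0)

    def test_gct_starts_with_version_line(self, tmp_path, small_matrix):
        path = tmp_path / "m.gct"
        write_expression(small_matrix, str(path), format="gct")
        assert path.read_text().startswith("#1.2\n")

    def test_gct_row_count_mismatch_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.2\n3\t1\nName\tDescription\ts1\ng1\tna\t1\ng2\tna\t2\n")
        with pytest.raises(ParseError, match="declares 3"):
            read_expression(str(path), format="gct")

    def test_non_numeric_cell_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\ts1\ng1\t1.0\ng2\toops\n")
        with pytest.raises(ParseError, match=":3"):
            read_expression(str(path), format="tsv")

    def test_missing_gct_header_rejected(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("2\t1\nName\tDescription\ts1\n")
        with pytest.raises(ParseError, match="#1.2"):
            read_expression(str(path), format="gct")

    def test_empty_sample_list_rejected_on_write(self, tmp_path):
        m = ExpressionMatrix(["g1"], [], np.empty((1, 0)))
        with pytest.raises(ValueError, match="no samples"):
            write_expression(m, str(tmp_path / "m.gct"))

    def test_duplicate_probe_ids_allowed_on_read(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\tp\np1\t1\t2\np1\t3\t4\n")
        m = read_expression(str(path), format="tsv")
        assert m.gene_ids == ["p1", "p1"]

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ExpressionMatrix(["g1"], ["s1"], np.array([[np.nan]]))


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

class TestReadGmt:
    def test_up_dn_merge(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text(
            "OSAP_UP\tdesc\tQPRT\tAPOE\n"
            "OSAP_DN\tdesc\tCCL20\tCXCL1\tCXCL2\n"
        )
        sigs = read_gmt(str(path))
        assert len(sigs) == 1
        sig = sigs[0]
        assert sig.name == "OSAP"
        assert sig.up == ["QPRT", "APOE"]
        assert sig.down == ["CCL20", "CXCL1", "CXCL2"]

    def test_single_plain_set_is_up_only(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S\td\tg1\n")
        (sig,) = read_gmt(str(path))
        assert sig.up == ["g1"] and sig.down == []

    def test_gene_in_both_sides_violates_disjointness(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S_UP\td\tg1\tg2\nS_DN\td\tg2\n")
        with pytest.raises(ValueError, match="both up and down"):
            read_gmt(str(path))

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("A\td\tg1\nB\td\n")
        with pytest.raises(ParseError, match=":2"):
            read_gmt(str(path))

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("A\td\tg1\nA\td\tg2\n")
        with pytest.raises(ParseError, match="duplicate set name"):
            read_gmt(str(path))

    def test_write_read_round_trip(self, tmp_path):
        sig = GeneSignature("S", up=["a", "b"], down=["c"])
        path = tmp_path / "s.gmt"
        write_gmt([sig], str(path))
        (back,) = read_gmt(str(path))
        assert back.name == "S" and back.up == sig.up and back.down == sig.down


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_two_sample_analytic_case(self):
        m = ExpressionMatrix(
            ["g1", "g2", "g3"], ["a", "b"],
            np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        )
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_samples_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        m = ExpressionMatrix(["g1", "g2", "g3"], ["a", "b"],
                             np.column_stack([col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)

    def test_all_sorted_columns_identical(self, random_matrix):
        out = quantile_normalize(random_matrix)
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, out.n_samples):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)

    def test_idempotent(self, random_matrix):
        once = quantile_normalize(random_matrix)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_preserves_within_sample_order(self, random_matrix):
        out = quantile_normalize(random_matrix)
        for j in range(out.n_samples):
            before = np.argsort(random_matrix.values[:, j], kind="stable")
            after = np.argsort(out.values[:, j], kind="stable")
            np.testing.assert_array_equal(before, after)

    def test_ties_get_mean_of_target_quantiles(self):
        m = ExpressionMatrix(
            ["g1", "g2", "g3"], ["a", "b"],
            np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]),
        )
        out = quantile_normalize(m)
        # reference = mean of sorted columns = [5.5, 10.5, 17.5]
        # column a ties at positions 1,2 -> both get (5.5+10.5)/2 = 8.0
        np.testing.assert_allclose(out.values[:, 0], [8.0, 8.0, 17.5])
        np.testing.assert_allclose(out.values[:, 1], [5.5, 10.5, 17.5])

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(["g1", "g2"], ["a"], np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match=">=2 samples"):
            quantile_normalize(m)


# ---------------------------------------------------------------------------
# probe collapse
# ---------------------------------------------------------------------------

class TestCollapseProbes:
    def test_max_mean_probe_wins(self):
        m = ExpressionMatrix(
            ["p1", "p2"], ["s1", "s2"],
            np.array([[4.0, 6.0], [6.0, 8.0]]),  # means 5.0 and 7.0
        )
        out = collapse_probes(m, {"p1": "G", "p2": "G"})
        assert out.gene_ids == ["G"]
        np.testing.assert_allclose(out.values[0], [6.0, 8.0])

    def test_one_to_one_mapping_renames_only(self, small_matrix):
        mapping = {p: p.upper() for p in small_matrix.gene_ids}
        out = collapse_probes(small_matrix, mapping)
        assert out.gene_ids == sorted(mapping.values())
        frame_in = small_matrix.to_frame().rename(index=mapping)
        np.testing.assert_allclose(out.to_frame().loc[out.gene_ids].values,
                                   frame_in.loc[out.gene_ids].values)

    def test_tie_broken_by_probe_id(self):
        m = ExpressionMatrix(
            ["pB", "pA"], ["s1"],
            np.array([[5.0], [5.0]]),
        )
        out = collapse_probes(m, {"pA": "G", "pB": "G"})
        # equal means: lexicographically first probe (pA) wins
        np.testing.assert_allclose(out.values[0], [5.0])
        assert out.gene_ids == ["G"]

    def test_unmapped_probes_dropped(self, small_matrix):
        out = collapse_probes(small_matrix, {"g1": "X"})
        assert out.gene_ids == ["X"]

    def test_row_count_equals_distinct_genes(self, random_matrix, rng):
        genes = [f"GENE{i}" for i in range(10)]
        mapping = {p: genes[i % 10] for i, p in enumerate(random_matrix.gene_ids)}
        out = collapse_probes(random_matrix, mapping)
        assert out.n_genes == len(set(mapping.values()))
        assert len(set(out.gene_ids)) == out.n_genes

    def test_empty_mapping_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(small_matrix, {})


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

def test_sample_table_round_trip(tmp_path):
    path = tmp_path / "anno.tsv"
    path.write_text(
        "sample_id\tgroup\tcohort\tstemness\n"
        "s1\thealthy\tA\t0.1\n"
        "s2\tdisease\tA\t0.9\n"
    )
    table = read_sample_table(str(path))
    assert table.samples_in_group("healthy") == ["s1"]
    assert table.groups() == ["healthy", "disease"]
    assert table.covariate("stemness").tolist() == [0.1, 0.9]


def test_sample_table_requires_group_and_cohort(tmp_path):
    path = tmp_path / "anno.tsv"
    path.write_text("sample_id\tgroup\ns1\thealthy\n")
    with pytest.raises(ValueError, match="cohort"):
        read_sample_table(str(path))
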