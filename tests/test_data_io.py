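import numpy as np
import pandas as pd
import pytest

from aracne_kit import (
    ExpressionMatrix,
    NetworkTable,
    read_expression,
    read_network,
    read_tf_list,
    write_expression,
    write_network,
)


def write_tsv(tmp_path, text, name="expr.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER8 = "gene\t" + "\t".join(f"s{j}" for j in range(8))
ROW8 = "\t".join(str(v) for v in range(8))


class TestReadExpression:
    def test_well_formed(self, tmp_path):
        path = write_tsv(tmp_path, f"{HEADER8}\nA\t{ROW8}\nB\t{ROW8}\nC\t{ROW8}\n")
        m = read_expression(path)
        assert m.gene_ids == ["A", "B", "C"]
        assert m.n_samples == 8
        assert m.values[1, 3] == 3.0

    def test_small_matrix_allowed_when_relaxed(self, tmp_path):
        path = write_tsv(tmp_path, "gene\ts0\ts1\ts2\ts3\nA\t1\t2\t3\t4\n")
        m = read_expression(path, min_samples=4)
        assert m.n_samples == 4
        with pytest.raises(ValueError, match="samples"):
            read_expression(path)

    def test_duplicate_gene_id(self, tmp_path):
        path = write_tsv(tmp_path, f"{HEADER8}\nA\t{ROW8}\nA\t{ROW8}\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression(path)

    def test_missing_cell_names_row_and_column(self, tmp_path):
        row = "\t".join(["1"] * 7)  # one field short
        path = write_tsv(tmp_path, f"{HEADER8}\nA\t{ROW8}\nB\t{row}\n")
        with pytest.raises(ValueError, match=r"'B'.*'s7'"):
            read_expression(path)

    def test_non_numeric_cell(self, tmp_path):
        bad = ROW8.replace("5", "oops")
        path = write_tsv(tmp_path, f"{HEADER8}\nA\t{bad}\n")
        with pytest.raises(ValueError, match="'A'"):
            read_expression(path)

    def test_roundtrip_identity(self, tmp_path, small_matrix):
        path = tmp_path / "m.tsv"
        write_expression(small_matrix, path)
        back = read_expression(path)
        assert back.gene_ids == small_matrix.gene_ids
        assert back.sample_ids == small_matrix.sample_ids
        np.testing.assert_allclose(back.values, small_matrix.values, rtol=1e-9)


class TestReadTFList:
    def test_all_present(self, tmp_path, small_matrix):
        path = write_tsv(tmp_path, "g0\ng1\n", "tfs.txt")
        assert set(read_tf_list(path, small_matrix).tf_indices) == {0, 1}

    def test_absent_gene_skipped_with_warning(self, tmp_path, small_matrix, caplog):
        path = write_tsv(tmp_path, "g0\nNOPE\n", "tfs.txt")
        with caplog.at_level("WARNING"):
            tfs = read_tf_list(path, small_matrix)
        assert set(tfs.tf_indices) == {0}
        assert any("NOPE" in rec.message for rec in caplog.records)

    def test_no_gene_present_is_error(self, tmp_path, small_matrix):
        path = write_tsv(tmp_path, "NOPE\n", "tfs.txt")
        with pytest.raises(ValueError):
            read_tf_list(path, small_matrix)

    def test_comments_and_blank_lines_ignored(self, tmp_path, small_matrix):
        path = write_tsv(tmp_path, "# header\n\ng2  # trailing\n", "tfs.txt")
        assert set(read_tf_list(path, small_matrix).tf_indices) == {2}


class TestNetworkTable:
    def edge_table(self):
        return NetworkTable(
            pd.DataFrame(
                {
                    "Regulator": ["t1"],
                    "Target": ["g1"],
                    "MI": [0.5],
                    "Count": [10],
                    "AdjPvalue": [1e-9],
                }
            )
        )

    def test_empty_network_writes_header_only(self, tmp_path):
        path = tmp_path / "net.tsv"
        write_network(NetworkTable(), path)
        assert path.read_text() == "Regulator\tTarget\tMI\tCount\tAdjPvalue\n"

    def test_single_edge_two_lines(self, tmp_path):
        path = tmp_path / "net.tsv"
        write_network(self.edge_table(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[1] == "t1\tg1\t0.5\t10\t1e-09"

    def test_write_is_deterministic(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_network(self.edge_table(), p1)
        write_network(self.edge_table(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_roundtrip_preserves_edges_to_printed_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "Regulator": [f"t{i % 3}" for i in range(9)],
                "Target": [f"g{i}" for i in range(9)],
                "MI": rng.uniform(0.0, 2.0, 9),
                "Count": rng.integers(1, 11, 9),
                "AdjPvalue": rng.uniform(0.0, 1.0, 9),
            }
        )
        path = tmp_path / "net.tsv"
        write_network(NetworkTable(df), path)
        back = read_network(path).rows.set_index(["Regulator", "Target"])
        orig = df.set_index(["Regulator", "Target"])
        assert set(back.index) == set(orig.index)
        joined = orig.join(back, lsuffix="_o")
        np.testing.assert_allclose(joined["MI_o"], joined["MI"], rtol=1e-5)
        assert (joined["Count_o"] == joined["Count"]).all()

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self"):
            NetworkTable(
                pd.DataFrame(
                    {
                        "Regulator": ["a"],
                        "Target": ["a"],
                        "MI": [0.1],
                        "Count": [1],
                        "AdjPvalue": [np.nan],
                    }
                )
            )


class TestExpressionMatrixInvariants:
    def test_nan_rejected_with_location(self):
        values = np.ones((2, 8))
        values[1, 2] = np.nan
        with pytest.raises(ValueError, match=r"'b'.*'s2'"):
            ExpressionMatrix(["a", "b"], [f"s{j}" for j in range(8)], values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(["a"], ["s0", "s1"], np.ones((2, 2)))
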