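import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dielnet.preprocess import (
    ExpressionMatrix,
    collapse_replicates,
    filter_background,
    parse_sample_label,
    quantile_normalize,
    read_expression,
    write_expression,
)


class TestReadWrite:
    def test_round_trip(self, small_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_expression(small_matrix, path)
        back = read_expression(path)
        pd.testing.assert_frame_equal(
            back.values, small_matrix.values, check_names=False
        )
        assert np.array_equal(back.zt, small_matrix.zt)
        assert np.array_equal(back.replicate, small_matrix.replicate)

    def test_basic_shape(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tZT00_r1\tZT04_r1\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        m = read_expression(path)
        assert m.values.shape == (3, 2)
        assert list(m.zt) == [0.0, 4.0]

    def test_duplicate_gene_id_names_offender(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tZT00_r1\ngX\t1\ngX\t2\n")
        with pytest.raises(ValueError, match="gX"):
            read_expression(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tZT00_r1\tZT04_r1\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(ValueError):
            read_expression(path)

    def test_unparseable_sample_label(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tsampleA\ng1\t1\n")
        with pytest.raises(ValueError, match="sampleA"):
            read_expression(path)

    @pytest.mark.parametrize(
        "label,expected", [("ZT04_r2", (4.0, 2)), ("ZT20_r1", (20.0, 1))]
    )
    def test_parse_sample_label(self, label, expected):
        assert parse_sample_label(label) == expected


class TestQuantileNormalize:
    def _mat(self, cols):
        arr = np.array(cols, dtype=float).T
        values = pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"ZT{4*j:02d}_r1" for j in range(arr.shape[1])],
        )
        return ExpressionMatrix(
            values,
            zt=np.array([4.0 * j for j in range(arr.shape[1])]),
            replicate=np.ones(arr.shape[1], dtype=int),
        )

    def test_hand_computed_rank_means(self):
        m = self._mat([[1, 3, 2], [4, 6, 5]])
        out = quantile_normalize(m).values.to_numpy()
        expected = np.array([[2.5, 2.5], [4.5, 4.5], [3.5, 3.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_unchanged(self):
        m = self._mat([[1, 5, 3], [1, 5, 3]])
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, m.values.to_numpy())

    def test_single_column_unchanged(self):
        m = self._mat([[7, 1, 4]])
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, m.values.to_numpy())

    def test_ties_get_mean_of_rank_targets(self):
        m = self._mat([[1, 1, 5], [2, 4, 6]])
        out = quantile_normalize(m).values.to_numpy()
        # rank targets are (1.5, 2.5, 5.5); the tie at ranks 1-2 averages to 2
        np.testing.assert_allclose(out[:, 0], [2.0, 2.0, 5.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 2.5, 5.5])

    @given(
        st.lists(
            st.lists(
                st.floats(0.0, 1e4), min_size=5, max_size=5, unique=True
            ),
            min_size=2,
            max_size=4,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_idempotent_and_rank_preserving(self, cols):
        # idempotence holds exactly for tie-free columns
        m = self._mat(cols)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9
        )
        a, b = m.values.to_numpy(), once.values.to_numpy()
        for j in range(a.shape[1]):
            order_in = np.argsort(a[:, j], kind="mergesort")
            assert np.all(np.diff(b[order_in, j]) >= -1e-12)

    def test_non_finite_rejected(self):
        m = self._mat([[1, np.inf, 3]])
        with pytest.raises(ValueError):
            quantile_normalize(m)


class TestFilterBackground:
    def _mat(self, rows):
        values = pd.DataFrame(
            np.array(rows, dtype=float),
            index=[f"g{i}" for i in range(len(rows))],
            columns=["ZT00_r1", "ZT04_r1"],
        )
        return ExpressionMatrix(
            values, zt=np.array([0.0, 4.0]), replicate=np.array([1, 1])
        )

    def test_below_cutoff_removed_and_counted(self):
        m = self._mat([[100, 100], [100, 200]])
        out, report = filter_background(m, 136.5)
        assert out.gene_ids == ["g1"]
        assert report["n_removed"] == 1 and report["n_kept"] == 1

    def test_single_sample_above_retains(self):
        m = self._mat([[10, 200]])
        out, _ = filter_background(m, 136.5)
        assert out.gene_ids == ["g0"]

    def test_zero_cutoff_retains_all(self):
        m = self._mat([[1, 1], [2, 2]])
        out, _ = filter_background(m, 0.0)
        assert out.n_genes == 2

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        m = self._mat(rng.uniform(50, 500, size=(20, 2)))
        kept = [
            filter_background(m, c)[0].n_genes for c in (0, 100, 200, 300, 600)
        ]
        assert kept == sorted(kept, reverse=True)

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_background(self._mat([[1, 1]]), -1.0)


class TestCollapseReplicates:
    def test_mean_and_se(self, small_matrix):
        collapsed, sem = collapse_replicates(small_matrix)
        assert collapsed.n_samples == 2
        np.testing.assert_allclose(collapsed.values.loc["gA"], [105.0, 195.0])
        np.testing.assert_allclose(
            sem.loc["gA"], [np.std([100, 110], ddof=1) / np.sqrt(2)] * 1 + [np.std([200, 190], ddof=1) / np.sqrt(2)],
        )

    def test_single_replicate_identity(self):
        values = pd.DataFrame(
            [[1.0, 2.0]], index=["g"], columns=["ZT00_r1", "ZT04_r1"]
        )
        m = ExpressionMatrix(values, zt=[0.0, 4.0], replicate=[1, 1])
        collapsed, sem = collapse_replicates(m)
        np.testing.assert_allclose(collapsed.values.to_numpy(), [[1.0, 2.0]])
        np.testing.assert_allclose(sem.to_numpy(), 0.0)

    def test_constant_replicates_zero_se(self):
        values = pd.DataFrame(
            [[3.0] * 4], index=["g"], columns=[f"ZT00_r{k}" for k in range(1, 5)]
        )
        m = ExpressionMatrix(values, zt=[0.0] * 4, replicate=[1, 2, 3, 4])
        collapsed, sem = collapse_replicates(m)
        assert collapsed.values.iloc[0, 0] == 3.0
        assert sem.iloc[0, 0] == 0.0
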