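import numpy as np
import pytest
from hypothesis import given, strategies as st

import spatialmap.datasets_io as dio
from spatialmap.datasets_io import (DataError, PairingError, SCDataset,
                                    SpatialDataset, filter_cells,
                                    filter_low_expression_genes, load_counts,
                                    pair_datasets,
                                    rescale_normalized_to_counts)


def _sc(counts, types=None, genes=None):
    counts = np.asarray(counts)
    m, p = counts.shape
    return SCDataset(
        counts=counts, cell_ids=[f"c{i}" for i in range(m)],
        gene_names=genes or [f"g{j}" for j in range(p)],
        cell_types=types or ["t"] * m)


class TestLoadCounts:
    def test_dense_roundtrip(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tgA\tgB\npx1\t1\t0\npx2\t2\t3\n")
        mat, rows, cols = load_counts(path)
        assert mat.tolist() == [[1, 0], [2, 3]]
        assert rows == ["px1", "px2"] and cols == ["gA", "gB"]

    def test_matrix_market_triplet(self, tmp_path):
        path = tmp_path / "m.mtx"
        path.write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 2 1\n1 1 5\n")
        (tmp_path / "m_rows.txt").write_text("r1\nr2\n")
        (tmp_path / "m_cols.txt").write_text("c1\nc2\n")
        mat, rows, cols = load_counts(path)
        assert mat.tolist() == [[5, 0], [0, 0]]
        assert rows == ["r1", "r2"] and cols == ["c1", "c2"]

    def test_negative_entry_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tgA\npx1\t-1\npx2\t2\n")
        with pytest.raises(DataError, match="negative"):
            load_counts(path)

    def test_non_numeric_entry_names_line(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tgA\npx1\t1\npx2\tabc\n")
        with pytest.raises(DataError, match="line 3"):
            load_counts(path)

    def test_write_load_fixpoint(self, tmp_path):
        rng = np.random.default_rng(3)
        mat = rng.poisson(2.0, size=(6, 4))
        for layout, name in (("dense", "a.tsv"), ("mtx", "a.mtx")):
            dio.write_counts(mat, [f"r{i}" for i in range(6)],
                             [f"c{j}" for j in range(4)],
                             tmp_path / name, layout)
            back, rows, cols = load_counts(tmp_path / name)
            assert np.array_equal(back, mat)
            assert rows == [f"r{i}" for i in range(6)]
            assert cols == [f"c{j}" for j in range(4)]


class TestSpatialDataset:
    def test_size_factors_are_row_sums(self):
        ds = SpatialDataset(counts=[[1, 2], [3, 4]], coords=[[0, 0], [1, 0]],
                            pixel_ids=["a", "b"], gene_names=["g1", "g2"])
        assert ds.size_factors.tolist() == [3.0, 7.0]

    def test_zero_count_pixel_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero total counts"):
            ds = SpatialDataset.from_arrays(
                [[1, 2], [0, 0], [3, 4]], [[0, 0], [1, 0], [2, 0]],
                ["a", "b", "c"], ["g1", "g2"])
        assert ds.pixel_ids == ["a", "c"]

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            SpatialDataset(counts=[[1, 2], [3, 4]], coords=[[0, 0], [1, 0]],
                           pixel_ids=["a", "b"], gene_names=["g", "g"])

    def test_roundtrip_through_files(self, tmp_path):
        rng = np.random.default_rng(5)
        ds = SpatialDataset(
            counts=rng.poisson(3.0, size=(5, 3)) + 1,
            coords=rng.uniform(0, 10, size=(5, 2)),
            pixel_ids=[f"p{i}" for i in range(5)],
            gene_names=["gA", "gB", "gC"])
        dio.write_spatial_dataset(ds, tmp_path)
        back = dio.load_spatial_dataset(tmp_path / "spatial_counts.tsv",
                                        tmp_path / "coords.tsv")
        assert np.array_equal(back.counts, ds.counts)
        assert back.pixel_ids == ds.pixel_ids
        assert back.gene_names == ds.gene_names
        assert np.allclose(back.coords, ds.coords)


class TestFilterCells:
    def test_depth_threshold_is_inclusive(self):
        sc = _sc([[9], [10], [11]], genes=["g"])
        out = filter_cells(sc, min_depth=10)
        assert out.cell_ids == ["c1", "c2"]
        assert np.all(out.depths >= 10)

    def test_excluded_label_removed_regardless_of_depth(self):
        sc = _sc([[100], [100]], types=["Ambiguous", "neuron"], genes=["g"])
        out = filter_cells(sc, min_depth=0, excluded_labels={"Ambiguous"})
        assert out.cell_types == ["neuron"]

    def test_noop_filter_is_identity(self):
        sc = _sc([[1, 2], [3, 4]])
        out = filter_cells(sc, min_depth=0, excluded_labels=())
        assert np.array_equal(out.counts, sc.counts)
        assert out.cell_ids == sc.cell_ids

    def test_all_cells_removed_raises(self):
        sc = _sc([[1], [2]], genes=["g"])
        with pytest.raises(DataError, match="every cell"):
            filter_cells(sc, min_depth=100)

    def test_remaining_depths_respect_threshold(self, rng):
        counts = rng.poisson(1.0, size=(40, 5))
        counts[:, 0] += 1  # keep at least one nonzero per cell
        sc = _sc(counts)
        out = filter_cells(sc, min_depth=4)
        assert np.all(out.depths >= 4)
        assert out.gene_names == sc.gene_names


class TestRescale:
    @pytest.mark.parametrize("value,scale,expected", [
        (0.0023, 1000, 3),    # ceil(2.3)
        (0.0, 1000, 0),       # zeros map to zeros
        (2.0, 1000, 2000),    # ceiling of an exact integer is itself
    ])
    def test_stated_rule(self, value, scale, expected):
        out = rescale_normalized_to_counts(np.array([[value]]), scale)
        assert out[0, 0] == expected

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            rescale_normalized_to_counts(np.array([[-0.1]]), 1000)

    @given(st.floats(min_value=0, max_value=1e4, allow_nan=False),
           st.floats(min_value=1e-3, max_value=1e4))
    def test_ceiling_brackets_the_product(self, v, s):
        out = rescale_normalized_to_counts(np.array([v]), s)[0]
        assert out == np.ceil(v * s)  # hence v*s <= out < v*s + 1 exactly
        assert out >= v * s - 1e-9
        assert out <= np.floor(v * s) + 1

    def test_volume_divisor_orders(self):
        vals = np.array([[0.004]])
        before = rescale_normalized_to_counts(vals, 1000, volume=[2.0],
                                              volume_adjust="before")
        after = rescale_normalized_to_counts(vals, 1000, volume=[2.0],
                                             volume_adjust="after")
        assert before[0, 0] == after[0, 0] == 2  # ceil(2.0)


class TestPairing:
    def test_intersection(self):
        sp = SpatialDataset(counts=[[1, 1, 1], [2, 2, 2]],
                            coords=[[0, 0], [1, 0]], pixel_ids=["a", "b"],
                            gene_names=["A", "B", "C"])
        sc = _sc([[1, 1, 1]], genes=["B", "C", "D"])
        paired = pair_datasets(sp, sc)
        assert paired.shared_genes == ["B", "C"]

    def test_symmetric_in_gene_content(self):
        sp = SpatialDataset(counts=[[1, 1], [2, 2]], coords=[[0, 0], [1, 0]],
                            pixel_ids=["a", "b"], gene_names=["X", "B"])
        sc = _sc([[1, 1, 1]], genes=["B", "X", "Q"])
        assert pair_datasets(sp, sc).shared_genes == sorted(
            set(sp.gene_names) & set(sc.gene_names))

    def test_disjoint_sets_raise(self):
        sp = SpatialDataset(counts=[[1], [2]], coords=[[0, 0], [1, 0]],
                            pixel_ids=["a", "b"], gene_names=["A"])
        sc = _sc([[1]], genes=["Z"])
        with pytest.raises(PairingError):
            pair_datasets(sp, sc)

    def test_identical_sets_lexicographic(self):
        genes = ["e", "a", "c", "b", "d"]
        sp = SpatialDataset(counts=np.ones((2, 5), int),
                            coords=[[0, 0], [1, 0]], pixel_ids=["a", "b"],
                            gene_names=genes)
        sc = _sc(np.ones((1, 5), int), genes=genes)
        assert pair_datasets(sp, sc).shared_genes == sorted(genes)


def test_low_expression_filter_drops_rare_genes():
    counts = np.zeros((100, 3), dtype=int)
    counts[:, 0] = 5          # everywhere
    counts[:50, 1] = 1        # half the pixels
    counts[0, 2] = 1          # a single pixel: below 5% threshold
    ds = SpatialDataset(counts=counts,
                        coords=np.c_[np.arange(100), np.zeros(100)],
                        pixel_ids=[f"p{i}" for i in range(100)],
                        gene_names=["common", "half", "rare"])
    out = filter_low_expression_genes(ds, min_nonzero_fraction=0.05)
    assert out.gene_names == ["common", "half"]
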