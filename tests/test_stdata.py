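"""Loading, gene selection, patch extraction, labels, normalization."""

import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse

from spotalign import (DataSplit, attach_labels, extract_patches, load_visium,
                       normalize_expression, select_top_genes)
from spotalign.stdata import write_labels
from spotalign.synthdata import load_dataset, write_dataset


# ------------------------------------------------------------ select_top_genes
def test_select_top_genes_stated_example():
    # per-gene totals [10, 5, 7, 1], r=2 -> indices [0, 2]
    expr = np.array([[10.0, 5.0, 7.0, 1.0], [0, 0, 0, 0], [0, 0, 0, 0]])
    sel = select_top_genes(expr, r=2)
    assert list(sel.indices) == [0, 2]


def test_select_top_genes_r_equals_d_is_full_sort():
    expr = np.array([[1.0, 4.0, 2.0, 3.0]])
    sel = select_top_genes(expr, r=4)
    assert list(sel.indices) == [1, 3, 2, 0]


def test_select_top_genes_matches_brute_force_sort(rng):
    expr = rng.poisson(3.0, size=(50, 200)).astype(float)
    sel = select_top_genes(expr, r=80)
    totals = expr.sum(axis=0)
    # independent oracle: stable sort on (-total, index)
    order = sorted(range(200), key=lambda j: (-totals[j], j))
    assert list(sel.indices) == order[:80]


def test_select_top_genes_invariant_to_spot_permutation(rng):
    expr = rng.poisson(2.0, size=(30, 50)).astype(float)
    sel1 = select_top_genes(expr, r=20)
    sel2 = select_top_genes(expr[rng.permutation(30)], r=20)
    assert sel1.indices == sel2.indices


def test_select_top_genes_tie_break_by_index():
    expr = np.array([[5.0, 5.0, 5.0]])
    assert list(select_top_genes(expr, r=3).indices) == [0, 1, 2]


def test_select_top_genes_errors(rng):
    with pytest.raises(ValueError):
        select_top_genes(np.ones((3, 4)), r=5)
    with pytest.raises(ValueError):
        select_top_genes(np.zeros((3, 4)), r=2)


def test_gene_selection_apply_no_recomputation_leakage(tiny_study):
    """Indices fitted on one slide, applied to another, subset identically."""
    (ds_a, _), (ds_b, _) = tiny_study
    sel = select_top_genes(ds_a.expression, r=10)
    h_direct = ds_b.expression[:, list(sel.indices)]
    np.testing.assert_array_equal(sel.apply(ds_b.expression), h_direct)


# ------------------------------------------------------------ normalization
def test_normalize_none_is_identity(rng):
    x = rng.poisson(5.0, size=(4, 6)).astype(float)
    np.testing.assert_array_equal(normalize_expression(x, "none"), x)


def test_normalize_median_scales_spot_totals():
    x = np.array([[50.0, 50.0], [150.0, 150.0]])   # totals 100, 300; median 200
    out = normalize_expression(x, "log1p_median")
    np.testing.assert_allclose(np.expm1(out).sum(axis=1), [200.0, 200.0])


def test_normalize_matches_reference_formula(rng):
    x = rng.poisson(4.0, size=(10, 8)).astype(float) + 1
    totals = x.sum(axis=1)
    ref = np.log1p(x / totals[:, None] * np.median(totals))
    np.testing.assert_allclose(normalize_expression(x, "log1p_median"), ref, atol=1e-12)


def test_normalize_unknown_mode():
    with pytest.raises(ValueError):
        normalize_expression(np.ones((2, 2)), "quantile")


# -------------------------------------------------------------- extract_patches
def _grid_dataset(coords_px, n_genes=3):
    from spotalign.stdata import STDataset
    n = len(coords_px)
    return STDataset(sample_id="s", barcodes=[f"b{i}" for i in range(n)],
                     expression=np.ones((n, n_genes)),
                     gene_ids=[f"g{i}" for i in range(n_genes)],
                     coords_px=np.asarray(coords_px, float),
                     coords_array=np.zeros((n, 2)))


def test_extract_patches_marker_at_center():
    img = np.zeros((512, 512, 3), dtype=np.float32)
    img[300, 200] = [1.0, 0.5, 0.25]
    ds = extract_patches(_grid_dataset([(300, 200)]), img, patch_px=224)
    np.testing.assert_allclose(ds.patches[0, :, 112, 112], [1.0, 0.5, 0.25])


def test_extract_patches_border_zero_padded(caplog):
    img = np.ones((512, 512, 3), dtype=np.float32)
    ds = extract_patches(_grid_dataset([(0, 0)]), img, patch_px=224)
    patch = ds.patches[0]
    assert (patch[:, :112, :] == 0).all() and (patch[:, :, :112] == 0).all()
    assert (patch[:, 112:, 112:] == 1).all()


def test_extract_patches_one_pixel_shift(rng):
    img = rng.random((256, 256, 3)).astype(np.float32)
    ds = extract_patches(_grid_dataset([(100, 100), (100, 101)]), img, patch_px=32)
    np.testing.assert_array_equal(ds.patches[0][:, :, 1:], ds.patches[1][:, :, :-1])


def test_extract_patches_center_recovers_pixel(rng):
    img = rng.random((256, 256, 3)).astype(np.float32)
    coords = [(64, 64), (128, 200), (30, 240)]
    ds = extract_patches(_grid_dataset(coords), img, patch_px=16)
    for i, (r, c) in enumerate(coords):
        np.testing.assert_allclose(ds.patches[i, :, 8, 8], img[r, c])


def test_extract_patches_outside_image_errors():
    img = np.ones((64, 64, 3), dtype=np.float32)
    with pytest.raises(ValueError, match="b0"):
        extract_patches(_grid_dataset([(500, 500)]), img, patch_px=16)


# ------------------------------------------------------------------ labels
def test_attach_labels_realigns_shuffled_rows(tiny_dataset, tmp_path):
    ds, _ = tiny_dataset
    df = pd.DataFrame(ds.abundances.copy(), index=ds.barcodes,
                      columns=ds.celltype_names)
    shuffled = df.sample(frac=1.0, random_state=1)
    out = attach_labels(ds, shuffled)
    np.testing.assert_array_equal(out.abundances, ds.abundances)


def test_attach_labels_rejects_negative(tiny_dataset):
    ds, _ = tiny_dataset
    df = pd.DataFrame(ds.abundances.copy(), index=ds.barcodes, columns=ds.celltype_names)
    df.iloc[0, 0] = -0.5
    with pytest.raises(ValueError, match="negative"):
        attach_labels(ds, df)


def test_attach_labels_missing_barcode(tiny_dataset):
    ds, _ = tiny_dataset
    df = pd.DataFrame(ds.abundances[1:], index=ds.barcodes[1:], columns=ds.celltype_names)
    with pytest.raises(ValueError, match=ds.barcodes[0]):
        attach_labels(ds, df)


def test_labels_write_read_roundtrip_bit_identical(tiny_dataset, tmp_path):
    ds, _ = tiny_dataset
    write_labels(ds, tmp_path / "labels.csv")
    out = attach_labels(ds, tmp_path / "labels.csv")
    np.testing.assert_array_equal(out.abundances, ds.abundances)


# ------------------------------------------------------------------ loading
def _write_toy_mtx(tmp_path, in_tissue=(1, 1, 0)):
    counts = scipy.sparse.csr_matrix(np.array([[3, 0, 1], [1, 2, 0], [0, 5, 4],
                                               [2, 2, 2]]))  # genes x spots
    scipy.io.mmwrite(tmp_path / "matrix.mtx", counts)
    pd.Series(["bcA", "bcB", "bcC"]).to_csv(tmp_path / "barcodes.tsv",
                                            index=False, header=False)
    pd.Series([f"g{i}" for i in range(4)]).to_csv(tmp_path / "features.tsv",
                                                  index=False, header=False)
    pos = pd.DataFrame({"barcode": ["bcA", "bcB", "bcC"],
                        "in_tissue": list(in_tissue),
                        "array_row": [0, 0, 1], "array_col": [0, 1, 0],
                        "pxl_row_in_fullres": [100, 100, 180],
                        "pxl_col_in_fullres": [100, 180, 140]})
    pos.to_csv(tmp_path / "tissue_positions.csv", index=False)
    return tmp_path


def test_load_visium_drops_out_of_tissue(tmp_path):
    d = _write_toy_mtx(tmp_path)
    ds = load_visium(d, d / "tissue_positions.csv")
    assert ds.n_spots == 2
    assert ds.barcodes == ["bcA", "bcB"]
    np.testing.assert_array_equal(ds.expression, np.array([[3, 1, 0, 2], [0, 2, 5, 2]]))


def test_load_visium_barcode_mismatch_names_offender(tmp_path):
    d = _write_toy_mtx(tmp_path)
    pos = pd.read_csv(d / "tissue_positions.csv")
    pos.loc[0, "barcode"] = "bcMISSING"
    pos.to_csv(d / "tissue_positions.csv", index=False)
    with pytest.raises(ValueError, match="bcMISSING"):
        load_visium(d, d / "tissue_positions.csv")


def test_synthetic_write_load_roundtrip(tiny_dataset, tmp_path):
    ds, truth = tiny_dataset
    write_dataset(ds, truth, tmp_path / "sample")
    back = load_dataset(tmp_path / "sample")
    assert back.sample_id == ds.sample_id
    assert back.barcodes == ds.barcodes
    np.testing.assert_array_equal(back.expression, ds.expression)
    np.testing.assert_array_equal(back.coords_px, ds.coords_px)
    np.testing.assert_array_equal(back.coords_array, ds.coords_array)
    np.testing.assert_array_equal(back.abundances, ds.abundances)
    np.testing.assert_array_equal(back.patches, ds.patches)
    assert back.celltype_names == ds.celltype_names
    assert back.gene_ids == ds.gene_ids


def test_h5ad_roundtrip(tiny_dataset, tmp_path):
    from spotalign.stdata import write_h5ad
    ds, _ = tiny_dataset
    write_h5ad(ds, tmp_path / "sample.h5ad")
    back = load_visium(tmp_path / "sample.h5ad")
    assert back.barcodes == ds.barcodes
    np.testing.assert_array_equal(back.expression, ds.expression)
    np.testing.assert_array_equal(back.abundances, ds.abundances)


# ------------------------------------------------------------------- splits
def test_datasplit_rejects_overlap():
    with pytest.raises(ValueError):
        DataSplit(train_ids=("a", "b"), val_ids=("b",))
    with pytest.raises(ValueError):
        DataSplit(train_ids=())
    s = DataSplit(train_ids=("a",), val_ids=("b",), test_ids=("c",))
    assert s.train_ids == ("a",)
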