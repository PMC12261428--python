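"""Spatial statistics: Moran's R/I, JSD, correlations, co-localization."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from spotalign import (bivariate_morans_r, build_weights, colocalization_matrix,
                       compare_colocalization, correlation_per_celltype,
                       jsd_per_celltype, top_partners)
from spotalign.spatialeval import ColocalizationMatrix, SpatialWeights, morans_i


def ring_weights(n=4):
    """n-node cycle, adjacent neighbors, row-standardized."""
    W = np.zeros((n, n))
    for i in range(n):
        W[i, (i - 1) % n] = 0.5
        W[i, (i + 1) % n] = 0.5
    return SpatialWeights(W=sp.csr_matrix(W), neighbor_rule="ring", row_standardized=True)


def brute_force_moran(a, b, W):
    """Double-loop oracle: sum_ij w_ij z_a,i z_b,j / n (population z-scores)."""
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    n = len(a)
    total = 0.0
    Wd = W.toarray()
    for i in range(n):
        for j in range(n):
            total += Wd[i, j] * za[i] * zb[j]
    return total / n


# -------------------------------------------------------------------- moran
def test_alternating_ring_is_exactly_minus_one():
    w = ring_weights(4)
    a = np.array([1.0, -1.0, 1.0, -1.0])
    assert bivariate_morans_r(a, a, w) == pytest.approx(-1.0, abs=1e-12)
    assert brute_force_moran(a, a, w.W) == pytest.approx(-1.0, abs=1e-12)


def test_self_pair_reduces_to_univariate_moran(rng):
    coords = rng.random((60, 2)) * 100
    w = build_weights(coords, k_neighbors=5)
    a = rng.normal(size=60)
    assert bivariate_morans_r(a, a, w) == pytest.approx(morans_i(a, w), abs=1e-14)
    assert bivariate_morans_r(a, a, w) == pytest.approx(brute_force_moran(a, a, w.W), abs=1e-10)


def test_matches_double_loop_oracle_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(20):
        n = int(rng.integers(10, 201))
        coords = rng.random((n, 2)) * 50
        w = build_weights(coords, k_neighbors=min(6, n - 1))
        a, b = rng.normal(size=n), rng.normal(size=n)
        got = bivariate_morans_r(a, b, w)
        assert got == pytest.approx(brute_force_moran(a, b, w.W), abs=1e-10)


def test_symmetry_for_symmetric_weights(rng):
    w = ring_weights(8)
    a, b = rng.normal(size=8), rng.normal(size=8)
    assert bivariate_morans_r(a, b, w) == pytest.approx(bivariate_morans_r(b, a, w), abs=1e-12)


def test_affine_invariance(rng):
    coords = rng.random((40, 2)) * 10
    w = build_weights(coords, k_neighbors=4)
    a, b = rng.normal(size=40), rng.normal(size=40)
    base = bivariate_morans_r(a, b, w)
    assert bivariate_morans_r(3.5 * a + 2.0, b, w) == pytest.approx(base, abs=1e-12)
    assert bivariate_morans_r(a, 0.1 * b - 7.0, w) == pytest.approx(base, abs=1e-12)


def test_zero_variance_input_errors():
    w = ring_weights(4)
    with pytest.raises(ValueError, match="zero-variance"):
        bivariate_morans_r(np.ones(4), np.arange(4.0), w)


# ------------------------------------------------------------------ weights
def test_weights_line_k1_symmetrized():
    coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0]])
    w = build_weights(coords, k_neighbors=1)
    A = w.W.toarray()
    assert A[0, 1] > 0 and A[3, 2] > 0
    # symmetrization adds the reciprocal edge 1->0 even though 1's nearest is 0 or 2
    assert (A > 0).sum(axis=1).min() >= 1
    np.testing.assert_allclose(A.sum(axis=1), 1.0)
    assert np.all(A.diagonal() == 0)


def test_weights_row_sums_one(rng):
    coords = rng.random((30, 2))
    w = build_weights(coords, k_neighbors=4)
    np.testing.assert_allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0)


def test_hex_grid_modal_neighbor_count_is_six(tiny_dataset):
    ds, _ = tiny_dataset
    coords = ds.coords_px
    w = build_weights(coords, k_neighbors=6)
    binary = (w.W > 0).astype(int)
    degrees = np.asarray(binary.sum(axis=1)).ravel()
    values, counts = np.unique(degrees, return_counts=True)
    assert values[np.argmax(counts)] == 6


def test_weights_too_few_spots():
    with pytest.raises(ValueError):
        build_weights(np.zeros((3, 2)), k_neighbors=6)


# --------------------------------------------------------------------- JSD
def test_jsd_identical_is_zero(rng):
    Y = rng.random((20, 4))
    np.testing.assert_allclose(jsd_per_celltype(Y, Y.copy()), 0.0, atol=1e-12)


def test_jsd_disjoint_support_is_one():
    Y = np.array([[1.0], [0.0]])
    Yh = np.array([[0.0], [1.0]])
    assert jsd_per_celltype(Y, Yh)[0] == pytest.approx(1.0, abs=1e-12)


def test_jsd_stated_value():
    # truth [1,0] vs prediction [0.5,0.5] -> 1 - 0.5*log2(... ) ~ 0.3113
    Y = np.array([[1.0], [0.0]])
    Yh = np.array([[0.5], [0.5]])
    got = jsd_per_celltype(Y, Yh)[0]
    # independent closed-form evaluation of base-2 JSD on ([1,0],[.5,.5])
    p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])
    m = (p + q) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = 0.5 * (np.nansum(p * np.log2(p / m)) + np.nansum(q * np.log2(q / m)))
    assert got == pytest.approx(expected, abs=1e-9)
    assert got == pytest.approx(0.3113, abs=2e-4)


def test_jsd_bounded_and_symmetric(rng):
    for _ in range(100):
        Y = rng.random((15, 3))
        Yh = rng.random((15, 3))
        j1 = jsd_per_celltype(Y, Yh)
        j2 = jsd_per_celltype(Yh, Y)
        assert np.all(j1 >= 0) and np.all(j1 <= 1)
        np.testing.assert_allclose(j1, j2, atol=1e-12)


def test_jsd_negative_predictions_clamped():
    Y = np.array([[1.0], [1.0]])
    Yh = np.array([[1.0], [-5.0]])   # clamps to [1, 0]
    expected = jsd_per_celltype(Y, np.array([[1.0], [0.0]]))
    np.testing.assert_allclose(jsd_per_celltype(Y, Yh), expected)


def test_jsd_all_zero_columns():
    Y = np.zeros((3, 1))
    assert jsd_per_celltype(Y, np.zeros((3, 1)))[0] == 0.0
    assert jsd_per_celltype(Y, np.ones((3, 1)))[0] == 1.0


# ------------------------------------------------------------- correlations
def test_correlation_identity_gives_ones(rng):
    Y = rng.random((30, 4))
    df = correlation_per_celltype(Y, Y.copy())
    body = df.drop(index="__mean__")
    np.testing.assert_allclose(body["spearman_rho"], 1.0)
    np.testing.assert_allclose(body["pcc"], 1.0)


def test_correlation_rank_reversal_gives_minus_one(rng):
    Y = rng.random((30, 2))
    Yh = -Y
    df = correlation_per_celltype(Y, Yh).drop(index="__mean__")
    np.testing.assert_allclose(df["spearman_rho"], -1.0)


def test_correlation_matches_scipy_reference(rng):
    Y = rng.random((100, 5))
    Yh = rng.random((100, 5))
    df = correlation_per_celltype(Y, Yh).drop(index="__mean__")
    for j in range(5):
        rho, p = spearmanr(Y[:, j], Yh[:, j])
        assert df["spearman_rho"].iloc[j] == pytest.approx(rho, abs=1e-10)
        assert df["spearman_p"].iloc[j] == pytest.approx(p, abs=1e-10)


def test_correlation_constant_column_excluded_from_mean(rng, caplog):
    Y = rng.random((30, 2))
    Yh = Y.copy()
    Yh[:, 1] = 5.0
    df = correlation_per_celltype(Y, Yh)
    assert np.isnan(df.loc[df.index[1], "spearman_rho"])
    assert df.loc["__mean__", "spearman_rho"] == pytest.approx(1.0)


def test_correlation_needs_three_spots(rng):
    with pytest.raises(ValueError):
        correlation_per_celltype(rng.random((2, 2)), rng.random((2, 2)))


# ---------------------------------------------------------- co-localization
def test_coloc_symmetric_for_symmetric_weights(rng):
    w = ring_weights(50)   # equal degrees: row-standardized W stays symmetric
    Y = rng.random((50, 4))
    C = colocalization_matrix(Y, w)
    np.testing.assert_allclose(C.values, C.values.T, atol=1e-12)


def test_coloc_diagonal_is_moran_i(rng):
    coords = rng.random((50, 2)) * 20
    w = build_weights(coords, k_neighbors=5)
    Y = rng.random((50, 4))
    C = colocalization_matrix(Y, w)
    for j in range(4):
        assert C.values[j, j] == pytest.approx(morans_i(Y[:, j], w), abs=1e-12)


def test_coloc_duplicated_column_duplicates_rows(rng):
    coords = rng.random((40, 2)) * 20
    w = build_weights(coords, k_neighbors=4)
    Y = rng.random((40, 3))
    Y[:, 2] = Y[:, 0]
    C = colocalization_matrix(Y, w)
    np.testing.assert_allclose(C.values[0], C.values[2], atol=1e-12)


def test_coloc_entries_match_pairwise_calls(rng):
    coords = rng.random((30, 2)) * 10
    w = build_weights(coords, k_neighbors=4)
    Y = rng.random((30, 3))
    C = colocalization_matrix(Y, w)
    for i in range(3):
        for j in range(3):
            assert C.values[i, j] == pytest.approx(
                bivariate_morans_r(Y[:, i], Y[:, j], w), abs=1e-12)


def test_shared_field_types_colocalize_more_than_independent(tiny_config):
    """Two abundance maps driven by one spatial field show higher pairwise R
    than two independent maps."""
    from spotalign.synthdata import gen_spatial_abundance
    truth = gen_spatial_abundance(tiny_config)
    w = build_weights(truth.coords_px)
    shared = truth.abundances[:, 0]
    rng = np.random.default_rng(5)
    coupled = shared * np.exp(0.1 * rng.normal(size=shared.size))
    Y = np.column_stack([shared, coupled, truth.abundances[:, 1]])
    C = colocalization_matrix(Y, w)
    assert C.values[0, 1] > C.values[0, 2]


def test_compare_colocalization_identity_and_negation(rng):
    vals = rng.normal(size=(4, 4))
    vals = (vals + vals.T) / 2
    names = list("abcd")
    C = ColocalizationMatrix(values=vals, celltype_names=names)
    Cn = ColocalizationMatrix(values=-vals, celltype_names=names)
    assert compare_colocalization(C, C) == (pytest.approx(1.0), pytest.approx(1.0))
    rho, cos = compare_colocalization(C, Cn)
    assert rho == pytest.approx(-1.0)
    assert cos == pytest.approx(-1.0)


def test_compare_colocalization_composition_oracle(rng):
    v1 = rng.normal(size=(5, 5))
    v2 = rng.normal(size=(5, 5))
    names = list("abcde")
    rho, cos = compare_colocalization(ColocalizationMatrix(v1, names),
                                      ColocalizationMatrix(v2, names))
    iu = np.triu_indices(5, k=1)
    a, b = v1[iu], v2[iu]
    assert rho == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)
    assert cos == pytest.approx(a @ b / np.linalg.norm(a) / np.linalg.norm(b), abs=1e-12)


def test_compare_colocalization_permutation_invariant(rng):
    vals = rng.normal(size=(4, 4))
    vals = (vals + vals.T) / 2
    v2 = vals + 0.1 * rng.normal(size=(4, 4))
    v2 = (v2 + v2.T) / 2
    names = list("abcd")
    base = compare_colocalization(ColocalizationMatrix(vals, names),
                                  ColocalizationMatrix(v2, names))
    perm = [2, 0, 3, 1]
    pn = [names[i] for i in perm]
    permuted = compare_colocalization(
        ColocalizationMatrix(vals[np.ix_(perm, perm)], pn),
        ColocalizationMatrix(v2[np.ix_(perm, perm)], pn))
    assert base[0] == pytest.approx(permuted[0], abs=1e-12)
    assert base[1] == pytest.approx(permuted[1], abs=1e-12)


def test_compare_colocalization_name_mismatch():
    C1 = ColocalizationMatrix(np.eye(2), ["a", "b"])
    C2 = ColocalizationMatrix(np.eye(2), ["a", "c"])
    with pytest.raises(ValueError):
        compare_colocalization(C1, C2)


# ------------------------------------------------------------- top partners
def test_top_partners_ranking_and_self_exclusion():
    vals = np.array([[0.9, 0.1, 0.5, 0.3],
                     [0.1, 0.8, 0.2, 0.6],
                     [0.5, 0.2, 0.7, 0.4],
                     [0.3, 0.6, 0.4, 0.9]])
    C = ColocalizationMatrix(vals, ["w", "x", "y", "z"])
    ranked = top_partners(C, "w", top_n=3)
    assert [name for name, _ in ranked] == ["y", "z", "x"]
    assert "w" not in [name for name, _ in ranked]
    full = top_partners(C, "x", top_n=3)
    assert len(full) == 3
    with pytest.raises(ValueError):
        top_partners(C, "nope")


# ------------------------------------------------------- hypothesis properties
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=40, deadline=None, derandomize=True)
@given(arrays(np.float64, (12, 3), elements=st.floats(0, 100)),
       arrays(np.float64, (12, 3), elements=st.floats(-50, 100)))
def test_jsd_bounds_hold_for_arbitrary_abundances(Y, Yh):
    j = jsd_per_celltype(Y, Yh)
    assert np.all(j >= 0.0) and np.all(j <= 1.0)
    np.testing.assert_allclose(j, jsd_per_celltype(np.maximum(Yh, 0), Y), atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0), st.integers(0, 5))
def test_moran_affine_invariance_property(scale, shift, seed):
    rng_local = np.random.default_rng(seed)
    coords = rng_local.random((25, 2)) * 10
    w = build_weights(coords, k_neighbors=4)
    a, b = rng_local.normal(size=25), rng_local.normal(size=25)
    base = bivariate_morans_r(a, b, w)
    assert bivariate_morans_r(scale * a + shift, b, w) == pytest.approx(base, abs=1e-9)
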