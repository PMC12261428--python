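"""Spatial evaluation of predicted cell-type abundance maps.

Covers the full downstream suite: per-cell-type Spearman/Pearson correlation
and Jensen-Shannon divergence between predicted and true abundances,
bivariate Moran's R spatial cross-correlation over a k-nearest-neighbor spot
graph, pairwise co-localization matrices, and comparison of global
co-localization patterns between truth and prediction.

Conventions
-----------
* Spatial weights: symmetric union of directed 6-NN (matching the Visium hex
  geometry), then row-standardized.
* Moran statistics use population (1/n) standard deviation for z-scoring and
  divisor n, so with row-standardized weights the univariate statistic is the
  familiar Moran's I and a 4-node alternating ring gives exactly -1.
* JSD is per cell type across spots, base-2 logs (range [0, 1]); negative
  predictions are clamped to zero before normalizing each type's spatial
  profile to a probability distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.special import rel_entr
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- types
@dataclass
class SpatialWeights:
    W: sp.csr_matrix              # (n, n) nonnegative, zero diagonal
    neighbor_rule: str
    row_standardized: bool

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class ColocalizationMatrix:
    values: np.ndarray            # (k, k) pairwise bivariate Moran's R
    celltype_names: list[str]
    leaf_order: list[int] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.celltype_names,
                            columns=self.celltype_names)


# ------------------------------------------------------------------- weights
def build_weights(coords: np.ndarray, k_neighbors: int = 6) -> SpatialWeights:
    """Symmetric k-NN spot graph with row-standardized weights.

    The directed k-NN graph (ties in distance broken by spot index, the
    KD-tree's stable order) is symmetrized by union, then each nonzero row is
    scaled to sum to 1.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} spots, got {n}")
    if pd.DataFrame(coords).duplicated().any():
        logger.warning("duplicate coordinates found; neighbor graph may be degenerate")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k_neighbors + 1)
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = idx[:, 1:].ravel()                      # drop self (nearest)
    A = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)                             # symmetrize by union
    A.setdiag(0)
    A.eliminate_zeros()
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    W = sp.diags(inv) @ A
    return SpatialWeights(W=W.tocsr(), neighbor_rule=f"knn{k_neighbors}_sym_union",
                          row_standardized=True)


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    sd = x.std()                                   # population std
    if sd == 0:
        raise ValueError(f"zero-variance input: {name}")
    return (x - x.mean()) / sd


def bivariate_morans_r(a: np.ndarray, b: np.ndarray, weights: SpatialWeights) -> float:
    """Spatial cross-correlation (z_a^T W z_b) / n.

    With a == b this is the univariate Moran's I.  Invariant to positive
    affine transforms of either argument.
    """
    za = _zscore(a, "a")
    zb = _zscore(b, "b")
    if za.size != weights.n or zb.size != weights.n:
        raise ValueError("vector length does not match weight matrix")
    return float(za @ (weights.W @ zb) / weights.n)


def morans_i(a: np.ndarray, weights: SpatialWeights) -> float:
    return bivariate_morans_r(a, a, weights)


# ----------------------------------------------------------------- JSD & rho
def _jsd_base2(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    val = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / np.log(2.0)
    return float(min(max(val, 0.0), 1.0))


def jsd_per_celltype(Y: np.ndarray, Y_hat: np.ndarray) -> np.ndarray:
    """Per-type Jensen-Shannon divergence between spatial abundance profiles.

    Each cell type's across-spot abundance vector (truth and prediction) is
    normalized to sum 1; negatives in the prediction are clamped first.  An
    all-zero profile scores 1 against any non-identical profile, 0 against an
    all-zero one.
    """
    Y = np.asarray(Y, dtype=np.float64)
    Y_hat = np.maximum(np.asarray(Y_hat, dtype=np.float64), 0.0)
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {Y_hat.shape}")
    k = Y.shape[1]
    out = np.empty(k)
    for j in range(k):
        p, q = Y[:, j], Y_hat[:, j]
        sp_, sq = p.sum(), q.sum()
        if sp_ == 0 and sq == 0:
            out[j] = 0.0
        elif sp_ == 0 or sq == 0:
            out[j] = 1.0
        else:
            out[j] = _jsd_base2(p / sp_, q / sq)
    return out


def correlation_per_celltype(Y: np.ndarray, Y_hat: np.ndarray,
                             celltype_names: list[str] | None = None) -> pd.DataFrame:
    """Per-type Spearman rho (two-sided t-approximation p-value), Pearson r
    and JSD, plus an unweighted mean row (constant columns excluded, logged)."""
    Y = np.asarray(Y, dtype=np.float64)
    Y_hat = np.asarray(Y_hat, dtype=np.float64)
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {Y_hat.shape}")
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 spots for correlation metrics")
    k = Y.shape[1]
    names = celltype_names or [f"type_{i}" for i in range(k)]
    jsd = jsd_per_celltype(Y, Y_hat)
    rows = []
    for j in range(k):
        a, b = Y[:, j], Y_hat[:, j]
        if a.std() == 0 or b.std() == 0:
            logger.warning("constant abundance column %r; correlations undefined", names[j])
            rows.append({"celltype": names[j], "spearman_rho": np.nan, "spearman_p": np.nan,
                         "pcc": np.nan, "jsd": jsd[j]})
            continue
        rho, p = spearmanr(a, b)
        pr = pearsonr(a, b).statistic
        rows.append({"celltype": names[j], "spearman_rho": float(rho),
                     "spearman_p": float(p), "pcc": float(pr), "jsd": jsd[j]})
    df = pd.DataFrame(rows).set_index("celltype")
    mean = df[["spearman_rho", "pcc", "jsd"]].mean(skipna=True)
    df.loc["__mean__"] = {"spearman_rho": mean["spearman_rho"], "spearman_p": np.nan,
                          "pcc": mean["pcc"], "jsd": mean["jsd"]}
    return df


# ------------------------------------------------------------ co-localization
def colocalization_matrix(Y: np.ndarray, weights: SpatialWeights,
                          celltype_names: list[str] | None = None,
                          cluster: bool = False) -> ColocalizationMatrix:
    """All pairwise bivariate Moran's R values between cell-type maps.

    The diagonal holds each type's univariate Moran's I.  Zero-variance
    columns yield NaN rows/columns with a warning.  With ``cluster=True`` an
    average-linkage hierarchical clustering on correlation distance provides
    a leaf order for heatmap display.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n, k = Y.shape
    names = celltype_names or [f"type_{i}" for i in range(k)]
    sd = Y.std(axis=0)
    ok = sd > 0
    if not ok.all():
        logger.warning("zero-variance columns flagged as missing: %s",
                       [names[i] for i in np.where(~ok)[0]])
    Z = np.zeros_like(Y)
    Z[:, ok] = (Y[:, ok] - Y[:, ok].mean(axis=0)) / sd[ok]
    vals = (Z.T @ (weights.W @ Z)) / n
    vals[~ok, :] = np.nan
    vals[:, ~ok] = np.nan
    leaf_order = None
    if cluster and ok.sum() >= 2:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import squareform
        sub = vals[np.ix_(ok, ok)]
        corr = np.corrcoef(sub)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        order_ok = leaves_list(average(squareform(dist, checks=False)))
        ok_idx = np.where(ok)[0]
        leaf_order = list(ok_idx[order_ok]) + list(np.where(~ok)[0])
        leaf_order = [int(i) for i in leaf_order]
    return ColocalizationMatrix(values=vals, celltype_names=list(names), leaf_order=leaf_order)


def compare_colocalization(C_true: ColocalizationMatrix,
                           C_pred: ColocalizationMatrix) -> tuple[float, float]:
    """Spearman rho and cosine similarity between the off-diagonal upper
    triangles of two co-localization matrices."""
    if C_true.celltype_names != C_pred.celltype_names:
        raise ValueError("cell-type names differ between matrices")
    iu = np.triu_indices_from(C_true.values, k=1)
    a, b = C_true.values[iu], C_pred.values[iu]
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    rho = float(spearmanr(a, b).statistic)
    cosine = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return rho, cosine


def top_partners(C: ColocalizationMatrix, celltype: str, top_n: int = 3) -> list[tuple[str, float]]:
    """The ``top_n`` other cell types most co-localized with ``celltype``,
    by descending Moran's R; ties break by name order."""
    if celltype not in C.celltype_names:
        raise ValueError(f"unknown cell type {celltype!r}")
    i = C.celltype_names.index(celltype)
    pairs = [(name, float(C.values[i, j])) for j, name in enumerate(C.celltype_names)
             if j != i]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return pairs[:top_n]


# ------------------------------------------------------------------- figures
def export_heatmap(C: ColocalizationMatrix, path, title: str = "") -> None:
    """Co-localization heatmap (clustered order when available)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = C.leaf_order or list(range(len(C.celltype_names)))
    vals = C.values[np.ix_(order, order)]
    names = [C.celltype_names[i] for i in order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-np.nanmax(np.abs(vals)),
                   vmax=np.nanmax(np.abs(vals)))
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=6)
    ax.set_yticks(range(len(names)), names, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="bivariate Moran's R")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def export_spatial_maps(coords: np.ndarray, Y_true: np.ndarray, Y_pred: np.ndarray,
                        celltype_names: list[str], outdir, max_types: int = 8) -> None:
    """Side-by-side truth/prediction scatter maps, shared color scale per type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for j, name in enumerate(celltype_names[:max_types]):
        vmax = max(Y_true[:, j].max(), Y_pred[:, j].max(), 1e-12)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharex=True, sharey=True)
        for ax, vals, label in zip(axes, (Y_true[:, j], Y_pred[:, j]), ("truth", "prediction")):
            scatter = ax.scatter(coords[:, 1], -coords[:, 0], c=vals, s=12,
                                 cmap="viridis", vmin=0, vmax=vmax)
            ax.set_title(f"{name} ({label})", fontsize=8)
            ax.set_aspect("equal")
        fig.colorbar(scatter, ax=axes, label="abundance")
        fig.savefig(outdir / f"map_{name}.png", dpi=120)
        plt.close(fig)
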