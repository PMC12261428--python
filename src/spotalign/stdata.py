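"""Reading and assembling Visium-style spatial-transcriptomics samples.

A sample couples four views of the same spots: a gene-count matrix, per-spot
full-resolution pixel positions from the ``tissue_positions.csv`` dialect, an
H&E image (whole-slide or pre-extracted per-spot patches), and optionally an
externally produced cell-type abundance matrix (e.g. deconvolution output)
that serves as the regression label.

The module also owns the gene-selection step (retain the top-r most highly
expressed genes, default r=250) and expression normalization feeding the
molecule encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                    "pxl_row_in_fullres", "pxl_col_in_fullres"]


# --------------------------------------------------------------------- types
@dataclass
class STDataset:
    """One ST sample: expression, coordinates, patches and optional labels."""

    sample_id: str
    barcodes: list[str]
    expression: np.ndarray                    # (n_spots, d) nonnegative counts
    gene_ids: list[str]
    coords_px: np.ndarray                     # (n_spots, 2) full-res (row, col)
    coords_array: np.ndarray                  # (n_spots, 2) hex-array (row, col)
    patches: np.ndarray | None = None         # (n_spots, 3, H, W) float32 in [0,1]
    abundances: np.ndarray | None = None      # (n_spots, k) nonnegative
    celltype_names: list[str] | None = None
    image_path: str | None = None

    def __post_init__(self):
        n = len(self.barcodes)
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.coords_px = np.asarray(self.coords_px, dtype=np.float64)
        self.coords_array = np.asarray(self.coords_array, dtype=np.float64)
        if self.expression.shape[0] != n:
            raise ValueError("expression row count != number of barcodes")
        if np.any(self.expression < 0):
            raise ValueError("expression contains negative entries")
        if len(self.gene_ids) != self.expression.shape[1]:
            raise ValueError("gene_ids length != expression columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if self.coords_px.shape != (n, 2) or self.coords_array.shape != (n, 2):
            raise ValueError("coordinate arrays must be (n_spots, 2)")
        if self.patches is not None:
            self.patches = np.asarray(self.patches, dtype=np.float32)
            if self.patches.shape[0] != n or self.patches.ndim != 4 or self.patches.shape[1] != 3:
                raise ValueError("patches must be (n_spots, 3, H, W)")
            if self.patches.shape[2] != self.patches.shape[3]:
                raise ValueError("patches must be square (H == W)")
        if self.abundances is not None:
            self.abundances = np.asarray(self.abundances, dtype=np.float64)
            if self.abundances.shape[0] != n:
                raise ValueError("abundances row count != number of spots")
            if np.any(self.abundances < 0):
                raise ValueError("abundances contain negative entries")
            if self.celltype_names is not None and len(self.celltype_names) != self.abundances.shape[1]:
                raise ValueError("celltype_names length != abundance columns")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


@dataclass(frozen=True)
class GeneSelection:
    """Ordered indices of the r retained genes (the psi mapping)."""

    indices: tuple[int, ...]
    criterion: str
    r: int

    def __post_init__(self):
        if len(self.indices) != self.r:
            raise ValueError("r != len(indices)")
        if len(set(self.indices)) != self.r:
            raise ValueError("gene indices not unique")

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        """Subset a (n, d) matrix to the retained genes, preserving order."""
        return np.asarray(matrix)[:, list(self.indices)]


@dataclass(frozen=True)
class DataSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...] = ()
    test_ids: tuple[str, ...] = ()

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("sample_id appears in more than one partition")
        if not self.train_ids:
            raise ValueError("empty train split")


# ------------------------------------------------------------------- loading
def _read_counts(counts_path: Path):
    """Return (barcodes, gene_ids, dense counts) from an MTX directory,
    a bare .mtx file with sibling barcodes/features TSVs, or an .h5ad."""
    import scipy.io
    import scipy.sparse

    counts_path = Path(counts_path)
    if counts_path.suffix == ".h5ad":
        import anndata
        adata = anndata.read_h5ad(counts_path)
        x = adata.X
        if scipy.sparse.issparse(x):
            x = x.toarray()
        return list(adata.obs_names), list(adata.var_names), np.asarray(x, dtype=np.float64), adata
    if counts_path.is_dir():
        mtx = counts_path / "matrix.mtx"
        bc = counts_path / "barcodes.tsv"
        ft = counts_path / "features.tsv"
    else:
        mtx = counts_path
        bc = counts_path.with_name("barcodes.tsv")
        ft = counts_path.with_name("features.tsv")
    mat = scipy.io.mmread(mtx)
    barcodes = pd.read_csv(bc, header=None, sep="\t")[0].astype(str).tolist()
    features = pd.read_csv(ft, header=None, sep="\t")[0].astype(str).tolist()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
    # MTX convention: genes x spots; transpose to spots x genes
    if dense.shape == (len(features), len(barcodes)):
        dense = dense.T
    elif dense.shape != (len(barcodes), len(features)):
        raise ValueError("matrix shape matches neither barcodes x features nor its transpose")
    return barcodes, features, dense, None


def read_positions(positions_path: Path) -> pd.DataFrame:
    """Read the tissue_positions.csv dialect; tolerates a header line."""
    first = pd.read_csv(positions_path, nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).lower() == "barcode"
    df = pd.read_csv(positions_path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise ValueError(f"positions file must have 6 columns, found {df.shape[1]}")
    df.columns = POSITION_COLUMNS
    df["barcode"] = df["barcode"].astype(str)
    return df


def load_visium(counts_path, positions_path=None, image_path=None,
                patches_dir=None, sample_id: str | None = None) -> STDataset:
    """Assemble an :class:`STDataset` from on-disk Visium-style inputs.

    Spots flagged out-of-tissue are dropped.  Spot order follows the counts
    matrix restricted to in-tissue barcodes.  ``image_path`` is recorded for a
    later :func:`extract_patches`; ``patches_dir`` loads pre-extracted
    ``<barcode>.png`` patch images immediately.
    """
    counts_path = Path(counts_path)
    barcodes, gene_ids, counts, adata = _read_counts(counts_path)

    if positions_path is None:
        if adata is None or not {"in_tissue", "array_row"}.issubset(adata.obs.columns):
            raise ValueError("positions_path is required unless the h5ad embeds positions")
        pos = adata.obs.reset_index().rename(columns={adata.obs.index.name or "index": "barcode"})
        pos = pos[POSITION_COLUMNS]
    else:
        pos = read_positions(Path(positions_path))

    count_set = set(barcodes)
    missing_in_counts = sorted(set(pos["barcode"]) - count_set)
    if missing_in_counts:
        raise ValueError(f"barcodes in positions but not in counts: {missing_in_counts}")
    pos_set = set(pos["barcode"])
    missing_in_pos = sorted(count_set - pos_set)
    if missing_in_pos:
        raise ValueError(f"barcodes in counts but not in positions: {missing_in_pos}")

    pos = pos.set_index("barcode").loc[barcodes].reset_index()
    keep = pos["in_tissue"].astype(int).to_numpy() == 1
    if not keep.any():
        raise ValueError("no in-tissue spots")
    kept = pos.loc[keep]
    kept_barcodes = kept["barcode"].tolist()
    row_idx = [barcodes.index(b) for b in kept_barcodes]

    patches = None
    if patches_dir is not None:
        from PIL import Image
        patches_dir = Path(patches_dir)
        imgs = []
        for b in kept_barcodes:
            f = patches_dir / f"{b}.png"
            if not f.exists():
                raise FileNotFoundError(f"patch image missing for barcode {b}: {f}")
            arr = np.asarray(Image.open(f).convert("RGB"), dtype=np.float32) / 255.0
            imgs.append(arr.transpose(2, 0, 1))
        patches = np.stack(imgs)

    ds = STDataset(
        sample_id=sample_id or counts_path.stem,
        barcodes=kept_barcodes,
        expression=counts[row_idx],
        gene_ids=gene_ids,
        coords_px=kept[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(dtype=np.float64),
        coords_array=kept[["array_row", "array_col"]].to_numpy(dtype=np.float64),
        patches=patches,
        image_path=str(image_path) if image_path is not None else None,
    )
    if adata is not None and "abundance" in getattr(adata, "obsm", {}):
        ab = pd.DataFrame(adata.obsm["abundance"], index=adata.obs_names)
        names = list(adata.uns.get("celltype_names", ab.columns.astype(str)))
        ds = replace(ds, abundances=ab.loc[kept_barcodes].to_numpy(dtype=np.float64),
                     celltype_names=names)
    return ds


# ----------------------------------------------------------- gene selection
def select_top_genes(expression: np.ndarray, r: int = 250,
                     criterion: str = "total_counts") -> GeneSelection:
    """Rank genes by total expression summed over spots; keep the top r.

    Order is descending total; ties break by ascending gene index, so the
    selection is deterministic and invariant to spot permutation.
    """
    expression = np.asarray(expression, dtype=np.float64)
    if np.any(expression < 0):
        raise ValueError("expression must be nonnegative")
    d = expression.shape[1]
    if r > d:
        raise ValueError(f"r={r} exceeds number of genes d={d}")
    if criterion == "total_counts":
        totals = expression.sum(axis=0)
    elif criterion == "mean_counts":
        totals = expression.mean(axis=0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not np.any(totals > 0):
        raise ValueError("expression matrix is all zero; no signal to rank")
    order = np.lexsort((np.arange(d), -totals))
    return GeneSelection(indices=tuple(int(i) for i in order[:r]), criterion=criterion, r=r)


# ----------------------------------------------------------------- patches
def extract_patches(dataset: STDataset, image, patch_px: int = 224,
                    scale: float = 1.0) -> STDataset:
    """Cut a ``patch_px`` square window centered at each spot.

    The window is the half-open square [c - P/2, c + P/2) on each axis at the
    working resolution (``scale`` maps full-res pixel coordinates to the
    loaded level; 1.0 means the image is at full resolution).  Windows
    overhanging the border are zero-padded with a logged warning; a spot whose
    center lies outside the image entirely is an error.
    """
    img = _load_image(image)
    Himg, Wimg = img.shape[:2]
    half = patch_px // 2
    out = np.zeros((dataset.n_spots, 3, patch_px, patch_px), dtype=np.float32)
    for i, (r_full, c_full) in enumerate(dataset.coords_px):
        r, c = int(round(r_full * scale)), int(round(c_full * scale))
        if not (0 <= r < Himg and 0 <= c < Wimg):
            raise ValueError(f"spot {dataset.barcodes[i]} center ({r}, {c}) outside image "
                             f"bounds ({Himg}, {Wimg})")
        r0, r1 = r - half, r - half + patch_px
        c0, c1 = c - half, c - half + patch_px
        rr0, rr1 = max(r0, 0), min(r1, Himg)
        cc0, cc1 = max(c0, 0), min(c1, Wimg)
        if (rr0, rr1, cc0, cc1) != (r0, r1, c0, c1):
            logger.warning("patch for spot %s overhangs image border; zero-padding",
                           dataset.barcodes[i])
        window = img[rr0:rr1, cc0:cc1]
        out[i, :, rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = window.transpose(2, 0, 1)
    return replace(dataset, patches=out)


def _load_image(image) -> np.ndarray:
    """Accept an array, PNG/TIFF path; return float32 (H, W, 3) in [0, 1]."""
    if isinstance(image, (str, Path)):
        p = Path(image)
        if p.suffix.lower() in {".tif", ".tiff"}:
            import tifffile
            arr = tifffile.imread(p)
        else:
            from PIL import Image
            arr = np.asarray(Image.open(p).convert("RGB"))
    else:
        arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr.astype(np.float32)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr[..., :3]


# ------------------------------------------------------------------- labels
def attach_labels(dataset: STDataset, labels) -> STDataset:
    """Attach a spots x cell-types abundance table, realigned by barcode.

    ``labels`` is a CSV path (barcode index in the first column) or a
    DataFrame indexed by barcode.  Missing barcodes and negative entries are
    hard errors.
    """
    if isinstance(labels, (str, Path)):
        # round_trip parser: written shortest-repr floats read back bit-identical
        df = pd.read_csv(labels, index_col=0, float_precision="round_trip")
    else:
        df = labels.copy()
    df.index = df.index.astype(str)
    missing = [b for b in dataset.barcodes if b not in df.index]
    if missing:
        raise ValueError(f"label table missing barcodes: {missing}")
    aligned = df.loc[dataset.barcodes]
    mat = aligned.to_numpy(dtype=np.float64)
    if np.any(mat < 0):
        bad = aligned.columns[np.any(mat < 0, axis=0)].tolist()
        raise ValueError(f"negative abundances in columns: {bad}")
    return replace(dataset, abundances=mat, celltype_names=[str(c) for c in aligned.columns])


def write_labels(dataset: STDataset, path) -> None:
    if dataset.abundances is None:
        raise ValueError("dataset has no abundances to write")
    cols = dataset.celltype_names or [f"type_{i}" for i in range(dataset.abundances.shape[1])]
    pd.DataFrame(dataset.abundances, index=pd.Index(dataset.barcodes, name="barcode"),
                 columns=cols).to_csv(path)


# ------------------------------------------------------------ normalization
def normalize_expression(expression: np.ndarray, mode: str = "log1p_median") -> np.ndarray:
    """Depth-normalize counts.

    ``log1p_median``: scale each spot to the median spot total, then log1p.
    ``log1p_cpm``: counts per million, then log1p.  ``none``: identity.
    """
    expression = np.asarray(expression, dtype=np.float64)
    if mode == "none":
        return expression.copy()
    totals = expression.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)
    if mode == "log1p_median":
        target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    elif mode == "log1p_cpm":
        target = 1e6
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return np.log1p(expression * (target / safe)[:, None])


# -------------------------------------------------------------------- h5ad
def write_h5ad(dataset: STDataset, path) -> None:
    """Write the assembled sample as one AnnData file (expression, positions,
    abundances); patches are stored separately as images."""
    import anndata

    obs = pd.DataFrame({
        "in_tissue": np.ones(dataset.n_spots, dtype=int),
        "array_row": dataset.coords_array[:, 0],
        "array_col": dataset.coords_array[:, 1],
        "pxl_row_in_fullres": dataset.coords_px[:, 0],
        "pxl_col_in_fullres": dataset.coords_px[:, 1],
    }, index=pd.Index(dataset.barcodes, name="barcode"))
    adata = anndata.AnnData(X=dataset.expression.astype(np.float64), obs=obs,
                            var=pd.DataFrame(index=dataset.gene_ids))
    if dataset.abundances is not None:
        adata.obsm["abundance"] = dataset.abundances
        adata.uns["celltype_names"] = list(dataset.celltype_names or [])
    adata.uns["sample_id"] = dataset.sample_id
    adata.write_h5ad(Path(path))
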