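"""Visium-like synthetic data with known ground-truth cell-type abundances.

The generator produces the three coupled views the cross-modal model trains
on, at desk scale and fully determined by a seed:

* **Abundances** — per cell type, a Gaussian-process draw on the hex grid
  (squared-exponential covariance, configurable lengthscale) is exponentiated
  and scaled by a Gamma-distributed per-type amplitude, giving smooth,
  nonnegative, spatially autocorrelated surfaces in the absolute-abundance
  style of deconvolution output (rows do not sum to 1).
* **Expression** — each spot's mean is its abundance row times a k x d
  signature matrix with marker-gene structure (``r_signal`` genes per type
  enriched 10x), scaled so the average spot depth is ``count_depth``; counts
  are negative-binomial with dispersion ``noise_dispersion`` (Poisson limit
  when infinite).
* **Patches** — "nuclei" (filled ellipses) are rendered as absorbing stains
  under a Beer-Lambert model: each nucleus adds its type's absorbance to an
  optical-density map and the image is ``background * exp(-density)``.
  Absorbances add, so overlapping nuclei darken instead of occluding, and the
  log-image is linear in per-type nucleus coverage — patch statistics are
  sufficient for the abundance vector up to counting noise.  Types are
  visually identified by hue, nucleus radius and stain intensity jointly
  (radius and intensity are anti-correlated: small nuclei stain dark, large
  ones pale, so each type carries comparable optical energy per nucleus).

A *study* (:func:`gen_study`) holds the type-level parameters fixed across
slides — signature matrix, palette and per-type amplitude scales are
biological properties of the cell types, not of a section — while each slide
draws fresh spatial fields, counts and renders.  This mirrors a multi-slide
Visium study deconvolved against a single scRNA reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stdata import STDataset

HEX_ROW_STEP = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_rows: int = 20
    n_cols: int = 20
    k: int = 8                      # cell types
    d: int = 300                    # genes
    r_signal: int = 5               # marker genes per type (10x enriched)
    dirichlet_alpha: float = 2.0    # shape of per-type Gamma amplitudes
    min_amplitude: float = 1.0      # amplitude floor: every type stays visible
    spatial_lengthscale: float = 2.0  # grid units
    count_depth: float = 1e4        # mean counts per spot
    noise_dispersion: float = 10.0  # NB dispersion; inf = Poisson
    patch_px: int = 64
    render_noise: float = 0.02      # pixel Gaussian noise std
    spot_spacing_px: int = 80       # full-res pixels between adjacent spots
    nuclei_per_unit: float = 8.0    # rendered nuclei per unit abundance
    seed: int = 0

    def __post_init__(self):
        if min(self.n_rows, self.n_cols, self.k, self.d, self.r_signal, self.patch_px) <= 0:
            raise ValueError("grid extents, k, d, r_signal and patch_px must be positive")
        if self.k > self.d:
            raise ValueError("k must not exceed d")
        if self.k * self.r_signal > self.d:
            raise ValueError("marker blocks (k*r_signal) exceed gene count d")
        if self.spatial_lengthscale <= 0 or self.count_depth <= 0 or self.noise_dispersion <= 0:
            raise ValueError("lengthscale, count_depth and noise_dispersion must be positive")

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class SyntheticTruth:
    abundances: np.ndarray          # (n_spots, k)
    signature: np.ndarray           # (k, d)
    palette: np.ndarray             # (k, 5): RGB color, nucleus radius, stain intensity
    coords_array: np.ndarray        # (n_spots, 2) hex (row, col)
    coords_px: np.ndarray           # (n_spots, 2) full-res (row, col)
    amplitudes: np.ndarray | None = None   # (k,) per-type scale of the surfaces


def hex_grid(n_rows: int, n_cols: int, spacing_px: float = 80.0):
    """Hex layout: odd rows offset by half a column; returns array and pixel
    coordinates (row, col), pixel origin at (spacing, spacing)."""
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    px_r = spacing_px * (1.0 + rows * HEX_ROW_STEP)
    px_c = spacing_px * (1.0 + cols + 0.5 * (rows % 2))
    return (np.stack([rows, cols], axis=1).astype(float),
            np.stack([px_r, px_c], axis=1))


def _unit_coords(coords_array: np.ndarray) -> np.ndarray:
    """Hex-array positions -> planar coordinates in grid units."""
    r, c = coords_array[:, 0], coords_array[:, 1]
    return np.stack([r * HEX_ROW_STEP, c + 0.5 * (r.astype(int) % 2)], axis=1)


@dataclass(frozen=True)
class TypeParams:
    """Study-level cell-type properties shared by every slide."""

    signature: np.ndarray           # (k, d)
    palette: np.ndarray             # (k, 5)
    amplitudes: np.ndarray          # (k,)


def draw_type_params(config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> TypeParams:
    """Signature matrix, rendering palette and amplitude scales for k types.

    Amplitudes are ``min_amplitude + Gamma(dirichlet_alpha, 1)``: a shifted
    Gamma, heterogeneous across types but floored so every type renders
    enough nuclei to remain observable in patches.
    """
    rng = rng or np.random.default_rng(config.seed)
    signature = _signature(config, rng)
    amps = config.min_amplitude + rng.gamma(shape=config.dirichlet_alpha, scale=1.0,
                                            size=config.k)
    return TypeParams(signature=signature, palette=_palette(config.k), amplitudes=amps)


def gen_spatial_abundance(config: SyntheticConfig,
                          rng: np.random.Generator | None = None,
                          type_params: TypeParams | None = None) -> SyntheticTruth:
    """Draw smooth nonnegative abundance surfaces over the hex grid.

    Per type: a zero-mean unit-variance Gaussian-process draw (squared
    exponential, ``spatial_lengthscale``), exponentiated and scaled by the
    type's amplitude — lognormal surfaces, spatially autocorrelated.
    """
    rng = rng or np.random.default_rng(config.seed)
    if type_params is None:
        type_params = draw_type_params(config, rng)
    coords_array, coords_px = hex_grid(config.n_rows, config.n_cols, config.spot_spacing_px)
    xy = _unit_coords(coords_array)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    K = np.exp(-0.5 * d2 / config.spatial_lengthscale**2)
    K[np.diag_indices_from(K)] += 1e-6
    L = np.linalg.cholesky(K)
    n = xy.shape[0]
    fields = L @ rng.normal(size=(n, config.k))          # GP draws, one per type
    fields = (fields - fields.mean(0)) / (fields.std(0) + 1e-12)
    abund = np.exp(fields) * type_params.amplitudes
    return SyntheticTruth(abundances=abund, signature=type_params.signature,
                          palette=type_params.palette, coords_array=coords_array,
                          coords_px=coords_px, amplitudes=type_params.amplitudes)


def _signature(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """k x d nonnegative signature; type t gets r_signal dedicated marker
    genes enriched 10x over the baseline expression level."""
    base = rng.uniform(0.05, 0.5, size=(config.k, config.d))
    for t in range(config.k):
        lo = t * config.r_signal
        base[t, lo:lo + config.r_signal] = 10.0 * rng.uniform(0.5, 1.0, size=config.r_signal)
    return base


def marker_genes(config: SyntheticConfig) -> np.ndarray:
    """(k, r_signal) indices of each type's dedicated marker genes."""
    return (np.arange(config.k)[:, None] * config.r_signal
            + np.arange(config.r_signal)[None, :])


def _palette(k: int) -> np.ndarray:
    """Deterministic per-type rendering parameters: hue from the HSV wheel,
    a unique nucleus radius, and a stain intensity that equalizes per-nucleus
    optical energy (intensity ~ 1/area, capped), so small-radius types render
    dark and large-radius types pale — every type carries comparable signal.

    Radii are interleaved against hue order so neighboring hues get very
    different sizes; hue, size and intensity jointly identify a type even
    though color space has only three channels.
    """
    h = np.arange(k) / k
    i = np.floor(h * 6).astype(int)
    f = h * 6 - i
    v, s = 0.85, 0.9
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    table = {0: (v, t, p), 1: (q, v, p), 2: (p, v, t), 3: (p, q, v), 4: (t, p, v), 5: (v, p, q)}
    rgb = np.zeros((k, 3))
    for j in range(k):
        comps = table[i[j] % 6]
        rgb[j] = [c[j] if isinstance(c, np.ndarray) else c for c in comps]
    idx = np.arange(k)
    order = idx // 2 + (idx % 2) * ((k + 1) // 2)   # e.g. k=8: [0,4,1,5,2,6,3,7]
    radius = 1.4 + 0.3 * order
    intensity = np.minimum(2.5, 20.0 / (np.pi * radius**2))
    return np.column_stack([rgb, radius, intensity])


def gen_expression(truth: SyntheticTruth, config: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample counts: NB around (abundance @ signature), global depth scaling."""
    rng = rng or np.random.default_rng(config.seed + 1)
    mean = truth.abundances @ truth.signature
    total = mean.sum(axis=1).mean()
    mu = mean * (config.count_depth / total)
    if np.isinf(config.noise_dispersion):
        return rng.poisson(mu).astype(np.float64)
    shape = config.noise_dispersion
    lam = rng.gamma(shape=shape, scale=np.maximum(mu, 1e-12) / shape)
    lam[mu <= 0] = 0.0
    return rng.poisson(lam).astype(np.float64)


def render_patches(truth: SyntheticTruth, config: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Render per-spot patch images encoding local abundance.

    Beer-Lambert stain model: every nucleus (an ellipse with its type's
    radius) adds ``intensity * absorbance_direction`` to a per-pixel optical
    density; the image is ``background * exp(-density)`` plus Gaussian pixel
    noise.  Nucleus counts are Poisson with mean
    ``nuclei_per_unit * abundance``, so doubling a type's abundance doubles
    its expected nucleus count.

    Returns (n_spots, 3, P, P) float32 in [0, 1], quantized to 8-bit so a PNG
    write/read round-trip is exact.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    P = config.patch_px
    n, k = truth.abundances.shape
    bg = np.array([0.92, 0.88, 0.92])          # pale tissue background
    dirs = 1.0 - truth.palette[:, :3]          # absorbance = complement of hue
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    absorb = truth.palette[:, 4][:, None] * dirs
    yy, xx = np.mgrid[0:P, 0:P]
    out = np.empty((n, 3, P, P), dtype=np.float32)
    for j in range(n):
        density = np.zeros((P, P, 3))
        for t in range(k):
            radius = truth.palette[t, 3]
            count = rng.poisson(config.nuclei_per_unit * truth.abundances[j, t])
            for _ in range(count):
                cy, cx = rng.uniform(0, P, size=2)
                ecc = rng.uniform(0.8, 1.25)
                mask = (((yy - cy) / (radius * ecc)) ** 2
                        + ((xx - cx) / radius) ** 2) <= 1.0
                density[mask] += absorb[t]
        img = bg * np.exp(-density)
        img = np.clip(img + rng.normal(0.0, config.render_noise, size=img.shape), 0.0, 1.0)
        img8 = np.round(img * 255.0).astype(np.uint8)
        out[j] = (img8.astype(np.float32) / 255.0).transpose(2, 0, 1)
    return out


def _assemble(config: SyntheticConfig, truth: SyntheticTruth, expr: np.ndarray,
              patches: np.ndarray, sample_id: str) -> STDataset:
    n = config.n_spots
    return STDataset(
        sample_id=sample_id,
        barcodes=[f"{sample_id}_SPOT{i:05d}" for i in range(n)],
        expression=expr,
        gene_ids=[f"gene_{i:04d}" for i in range(config.d)],
        coords_px=truth.coords_px,
        coords_array=truth.coords_array,
        patches=patches,
        abundances=truth.abundances,
        celltype_names=[f"celltype_{t:02d}" for t in range(config.k)],
    )


def gen_dataset(config: SyntheticConfig,
                sample_id: str = "synthetic") -> tuple[STDataset, SyntheticTruth]:
    """Compose abundances, expression and patches into one full sample."""
    ds, truth = gen_study(config, n_slides=1, sample_ids=[sample_id])[0]
    return ds, truth


def gen_study(config: SyntheticConfig, n_slides: int = 2,
              sample_ids: list[str] | None = None) -> list[tuple[STDataset, SyntheticTruth]]:
    """Generate a multi-slide study.

    Type-level parameters (signature matrix, palette, amplitude scales) are
    drawn once from ``config.seed`` and shared by all slides; each slide gets
    independent spatial fields, count noise and patch renders from seeds
    spawned deterministically off ``config.seed``.
    """
    if sample_ids is None:
        sample_ids = [f"slide{i:02d}" for i in range(n_slides)]
    if len(sample_ids) != n_slides:
        raise ValueError("sample_ids length must equal n_slides")
    root = np.random.SeedSequence(config.seed)
    study_seq, *slide_seqs = root.spawn(1 + n_slides)
    params = draw_type_params(config, np.random.default_rng(study_seq))
    out = []
    for sid, seq in zip(sample_ids, slide_seqs):
        f_seq, e_seq, p_seq = seq.spawn(3)
        truth = gen_spatial_abundance(config, np.random.default_rng(f_seq), params)
        expr = gen_expression(truth, config, np.random.default_rng(e_seq))
        patches = render_patches(truth, config, np.random.default_rng(p_seq))
        out.append((_assemble(config, truth, expr, patches, sid), truth))
    return out


def write_dataset(dataset: STDataset, truth: SyntheticTruth | None, outdir) -> Path:
    """Write a sample in the loader's own formats: MTX + barcodes/features,
    tissue_positions.csv, per-spot PNG patches, labels CSV, truth sidecars."""
    import scipy.io
    import scipy.sparse
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx",
                     scipy.sparse.csr_matrix(dataset.expression.T.astype(int)))
    pd.Series(dataset.barcodes).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    pd.Series(dataset.gene_ids).to_csv(outdir / "features.tsv", index=False, header=False)
    pos = pd.DataFrame({
        "barcode": dataset.barcodes,
        "in_tissue": 1,
        "array_row": dataset.coords_array[:, 0].astype(int),
        "array_col": dataset.coords_array[:, 1].astype(int),
        "pxl_row_in_fullres": dataset.coords_px[:, 0],
        "pxl_col_in_fullres": dataset.coords_px[:, 1],
    })
    pos.to_csv(outdir / "tissue_positions.csv", index=False)
    if dataset.patches is not None:
        pdir = outdir / "patches"
        pdir.mkdir(exist_ok=True)
        for b, patch in zip(dataset.barcodes, dataset.patches):
            arr = np.round(patch.transpose(1, 2, 0) * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(pdir / f"{b}.png")
    if dataset.abundances is not None:
        from .stdata import write_labels
        write_labels(dataset, outdir / "labels.csv")
    if truth is not None:
        np.savetxt(outdir / "truth_signature.tsv", truth.signature, delimiter="\t")
        np.savetxt(outdir / "truth_palette.tsv", truth.palette, delimiter="\t")
    meta = {"sample_id": dataset.sample_id, "n_spots": dataset.n_spots,
            "n_genes": dataset.n_genes,
            "k": None if dataset.abundances is None else int(dataset.abundances.shape[1])}
    (outdir / "sample_meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_dataset(outdir, sample_id: str | None = None) -> STDataset:
    """Re-load a directory written by :func:`write_dataset` via the Visium loader."""
    from .stdata import attach_labels, load_visium

    outdir = Path(outdir)
    meta = json.loads((outdir / "sample_meta.json").read_text())
    ds = load_visium(outdir, outdir / "tissue_positions.csv",
                     patches_dir=outdir / "patches" if (outdir / "patches").exists() else None,
                     sample_id=sample_id or meta["sample_id"])
    if (outdir / "labels.csv").exists():
        ds = attach_labels(ds, outdir / "labels.csv")
    return ds
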