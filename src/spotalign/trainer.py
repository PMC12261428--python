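"""End-to-end training of the cross-modal model and the image-only inference path.

Training minimizes ``lambda_C * L_C + lambda_A * L_A + lambda_G * L_G`` with
AdamW (decoupled weight decay = the optimizer-level L2 regularization).  Gene
selection is fitted on the training split only and travels with the model, so
validation/test expression is subset with the stored indices — never
re-ranked.  Inference consumes patches alone: the molecule branch and the
expression matrix are untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import objectives
from .encoders import (BackboneSpec, ModelBundle, build_bundle, molec_embed,
                       morph_embed, predict_abundance, reconstruct_expression)
from .nnx import AdamW, Tensor
from .objectives import LossReport, LossWeights, total_loss
from .stdata import DataSplit, GeneSelection, STDataset, normalize_expression, select_top_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    epochs: int = 20
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    weights: LossWeights = field(default_factory=LossWeights)
    align_variant: str = "rmse"
    seed: int = 0
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    d_a: int = 256
    r: int = 250
    norm_mode: str = "log1p_median"
    early_stop_patience: int = 10
    snn_hidden: int = 256
    snn_depth: int = 2
    snn_dropout: float = 0.1

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.r, self.d_a) <= 0:
            raise ValueError("batch_size, epochs, r and d_a must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class PredictionResult:
    """Per-spot abundance predictions with provenance.

    ``abundances`` is the raw regression output; ``abundances_clamped`` is the
    nonnegative copy intended for spatial analysis (flagged by ``clamped``).
    """

    abundances: np.ndarray
    coords_px: np.ndarray
    coords_array: np.ndarray
    barcodes: list[str]
    celltype_names: list[str]
    clamped: bool = False

    @property
    def abundances_clamped(self) -> np.ndarray:
        return np.maximum(self.abundances, 0.0)

    def to_frame(self, clamp: bool = True) -> pd.DataFrame:
        vals = self.abundances_clamped if clamp else self.abundances
        return pd.DataFrame(vals, index=pd.Index(self.barcodes, name="barcode"),
                            columns=self.celltype_names)


# ------------------------------------------------------------------ helpers
def _prepare_inputs(ds: STDataset, sel: GeneSelection, norm_mode: str) -> np.ndarray:
    """Normalized top-r gene submatrix for the molecule branch."""
    return sel.apply(normalize_expression(ds.expression, mode=norm_mode))


def _epoch_pass(bundle: ModelBundle, patches, h, y, cfg: TrainingConfig,
                optimizer: AdamW | None, rng: np.random.Generator | None) -> LossReport:
    """One pass over the data; trains when an optimizer is given."""
    n = patches.shape[0]
    order = rng.permutation(n) if rng is not None else np.arange(n)
    reports = []
    sizes = []
    for lo in range(0, n, cfg.batch_size):
        idx = order[lo:lo + cfg.batch_size]
        if len(idx) < 2:   # batch statistics (infonce, etc.) need >= 2 rows
            continue
        g = morph_embed(bundle, patches[idx])
        s = molec_embed(bundle, h[idx])
        y_hat = predict_abundance(bundle, g)
        h_hat = reconstruct_expression(bundle, s)
        l_c = objectives.alignment_loss(g, s, variant=cfg.align_variant)
        l_a = objectives.abundance_loss(Tensor(y[idx]), y_hat)
        l_g = objectives.reconstruction_loss(Tensor(h[idx]), h_hat)
        total, report = total_loss(l_c, l_a, l_g, cfg.weights, cfg.align_variant)
        if optimizer is not None:
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
        reports.append(report)
        sizes.append(len(idx))
    w = np.asarray(sizes, dtype=float)
    w /= w.sum()
    return LossReport(
        total=float(sum(r.total * wi for r, wi in zip(reports, w))),
        align=float(sum(r.align * wi for r, wi in zip(reports, w))),
        abundance=float(sum(r.abundance * wi for r, wi in zip(reports, w))),
        reconstruction=float(sum(r.reconstruction * wi for r, wi in zip(reports, w))),
        align_variant=cfg.align_variant)


def _stack_split(datasets: list[STDataset], ids: tuple[str, ...], sel: GeneSelection,
                 cfg: TrainingConfig):
    chosen = [d for d in datasets if d.sample_id in ids]
    if not chosen:
        return None
    for d in chosen:
        if d.patches is None:
            raise ValueError(f"dataset {d.sample_id} has no patches")
        if d.abundances is None:
            raise ValueError(f"dataset {d.sample_id} has no abundance labels")
    patches = np.concatenate([d.patches for d in chosen]).astype(np.float64)
    h = np.concatenate([_prepare_inputs(d, sel, cfg.norm_mode) for d in chosen])
    y = np.concatenate([d.abundances for d in chosen])
    return patches, h, y


# -------------------------------------------------------------------- train
def train(datasets: list[STDataset], split: DataSplit,
          config: TrainingConfig) -> tuple[ModelBundle, list[dict]]:
    """Fit the full model; returns the best-validation bundle and history.

    History rows carry per-epoch training and validation loss components.
    Model selection is by validation total loss (training loss when the split
    has no validation slides), with early stopping at
    ``early_stop_patience`` epochs without improvement.
    """
    by_id = {d.sample_id: d for d in datasets}
    unknown = [i for part in (split.train_ids, split.val_ids, split.test_ids)
               for i in part if i not in by_id]
    if unknown:
        raise ValueError(f"split references unknown sample_ids: {unknown}")

    train_sets = [by_id[i] for i in split.train_ids]
    sel = select_top_genes(np.concatenate([d.expression for d in train_sets]),
                           r=config.r)
    k = train_sets[0].abundances.shape[1] if train_sets[0].abundances is not None else None
    if k is None:
        raise ValueError("training datasets must carry abundance labels")

    bundle = build_bundle(config.backbone, d_a=config.d_a, r=config.r, k=k,
                          seed=config.seed, snn_hidden=config.snn_hidden,
                          snn_depth=config.snn_depth, snn_dropout=config.snn_dropout,
                          celltype_names=train_sets[0].celltype_names)
    bundle.gene_selection = sel
    bundle.norm_mode = config.norm_mode

    tr = _stack_split(datasets, split.train_ids, sel, config)
    va = _stack_split(datasets, split.val_ids, sel, config)

    optimizer = AdamW(bundle.trainable_parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)

    history: list[dict] = []
    best = (np.inf, None)
    stale = 0
    for epoch in range(config.epochs):
        bundle.train()
        tr_rep = _epoch_pass(bundle, *tr, config, optimizer, rng)
        bundle.eval()
        va_rep = _epoch_pass(bundle, *va, config, None, None) if va else tr_rep
        row = {"epoch": epoch, **{f"train_{k2}": v for k2, v in tr_rep.as_dict().items()
                                  if k2 != "align_variant"},
               **{f"val_{k2}": v for k2, v in va_rep.as_dict().items()
                  if k2 != "align_variant"}}
        history.append(row)
        logger.info("epoch %d train=%.4f val=%.4f", epoch, tr_rep.total, va_rep.total)
        if va_rep.total < best[0] - 1e-9:
            best = (va_rep.total, {name: mod.state_dict()
                                   for name, mod in bundle.modules().items()})
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    if best[1] is not None:
        for name, mod in bundle.modules().items():
            mod.load_state_dict(best[1][name])
    bundle.eval()
    return bundle, history


# -------------------------------------------------------------------- infer
def infer(bundle: ModelBundle, dataset: STDataset, batch_size: int = 64,
          clamp: bool = True) -> PredictionResult:
    """Image-only inference: y_hat = A(P(T(p))) per spot.

    Reads only ``dataset.patches`` and coordinates; expression and labels may
    be absent.
    """
    if dataset.patches is None:
        raise ValueError("dataset has no patches; run extract_patches first")
    bundle.eval()
    preds = []
    patches = dataset.patches.astype(np.float64)
    for lo in range(0, patches.shape[0], batch_size):
        g = morph_embed(bundle, patches[lo:lo + batch_size])
        preds.append(predict_abundance(bundle, g).numpy())
    raw = np.concatenate(preds)
    names = bundle.celltype_names or [f"type_{i}" for i in range(bundle.k)]
    out = raw if not clamp else np.maximum(raw, 0.0)
    return PredictionResult(abundances=out, coords_px=dataset.coords_px.copy(),
                            coords_array=dataset.coords_array.copy(),
                            barcodes=list(dataset.barcodes), celltype_names=list(names),
                            clamped=clamp)


def export_embeddings(bundle: ModelBundle, dataset: STDataset, which: str = "morph",
                      batch_size: int = 64) -> pd.DataFrame:
    """Spot embeddings for external visualization.

    ``morph`` needs patches; ``molec`` needs expression; ``crossmodal`` is the
    per-spot concatenation [g | s] and needs both.
    """
    if which not in {"morph", "molec", "crossmodal"}:
        raise ValueError(f"unknown embedding kind {which!r}")
    bundle.eval()
    blocks = []
    if which in {"morph", "crossmodal"}:
        if dataset.patches is None:
            raise ValueError("morphology embeddings require patches")
        g = [morph_embed(bundle, dataset.patches[lo:lo + batch_size].astype(np.float64)).numpy()
             for lo in range(0, dataset.n_spots, batch_size)]
        blocks.append(np.concatenate(g))
    if which in {"molec", "crossmodal"}:
        if dataset.expression is None or bundle.gene_selection is None:
            raise ValueError("molecule embeddings require expression and a fitted gene selection")
        h = _prepare_inputs(dataset, bundle.gene_selection, bundle.norm_mode)
        s = [molec_embed(bundle, h[lo:lo + batch_size]).numpy()
             for lo in range(0, dataset.n_spots, batch_size)]
        blocks.append(np.concatenate(s))
    mat = np.concatenate(blocks, axis=1)
    cols = [f"{which}_{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, index=pd.Index(dataset.barcodes, name="barcode"), columns=cols)
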