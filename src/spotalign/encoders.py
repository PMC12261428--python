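"""Model components: morphology and molecule encoders, heads, checkpointing.

Architecture
------------
* Morphology branch: a pluggable image backbone ``T`` (built-ins: ``tiny_cnn``
  and ``tiny_vit``; external pathology foundation models plug in behind the
  same interface) followed by a 2-layer projection head ``P`` producing
  embeddings ``g`` of width ``d_a``.  The backbone can be frozen outright or
  adapted with LoRA (low-rank updates on selected linear layers, zero at
  initialization).
* Molecule branch: a self-normalizing network ``S`` (SELU activations,
  lecun-normal init, alpha-dropout) over the normalized top-r gene vector,
  followed by a projection head ``H`` producing embeddings ``s`` of width
  ``d_a``.
* Heads: an MLP abundance regressor ``A`` (d_a -> k) on morphology embeddings
  and an expression decoder ``G`` (d_a -> r) on molecule embeddings.

Checkpoints are single ``.npz`` files holding every parameter array plus a
JSON metadata blob (dims, backbone spec, gene selection, cell-type names).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .nnx import (AlphaDropout, Conv2d, GlobalAvgPool2d, LayerNorm, Linear,
                  Module, SELU, Sequential, Tensor, as_tensor, concat, lora_wrap,
                  softmax)
from .stdata import GeneSelection

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


# --------------------------------------------------------------------- specs
@dataclass(frozen=True)
class LoRAConfig:
    rank: int = 8
    alpha: float = 16.0
    target_layers: str = "auto"   # fnmatch over qualified layer names
    dropout: float = 0.0

    def __post_init__(self):
        if self.rank <= 0 or self.alpha <= 0:
            raise ValueError("LoRA rank and alpha must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("LoRA dropout must be in [0, 1)")


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "tiny_cnn"
    feature_dim: int = 128
    frozen: bool = False
    lora: LoRAConfig | None = None
    input_px: int | None = None   # tiny_vit requires a fixed input side

    def default_lora_targets(self) -> str:
        return "*attn.w[qv]" if self.name == "tiny_vit" else "head"


# ----------------------------------------------------------------- backbones
class TinyCNN(Module):
    """3-block strided CNN with multi-scale pooling over an optical-density
    input transform.

    The input image is mapped to optical density (``-log`` of transmittance,
    the standard representation for stain quantification in histology) so
    stain amounts combine additively.  Features are the concatenated global
    average pools of all three conv stages plus a per-channel standard
    deviation pool of the last stage (second-order statistics carry stain
    covariance information that channel means alone cannot).  Accepts any
    square input of at least 16 px.
    """

    def __init__(self, feature_dim: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(3, 16, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(16, 32, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(32, 64, 3, rng, stride=2, padding=1)
        self.act = SELU()
        self.pool = GlobalAvgPool2d()
        self.head = Linear(16 + 32 + 64 + 64, feature_dim, rng)

    def forward(self, x):
        x = as_tensor(x)
        x = Tensor(-np.log(np.maximum(x.data, 0.02)))   # optical density
        h1 = self.act(self.conv1(x))
        h2 = self.act(self.conv2(h1))
        h3 = self.act(self.conv3(h2))
        m3 = self.pool(h3)
        center = m3.data.reshape(m3.shape[0], m3.shape[1], 1, 1)  # stop-grad mean
        v3 = (((h3 - center) ** 2).mean(axis=(2, 3)) + 1e-6) ** 0.5
        feats = concat([self.pool(h1), self.pool(h2), m3, v3], axis=1)
        return self.head(feats)


class _AttentionBlock(Module):
    """Pre-norm single-head self-attention + MLP block."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp1 = Linear(dim, 2 * dim, rng)
        self.mlp2 = Linear(2 * dim, dim, rng)
        self.act = SELU()
        self.scale = 1.0 / np.sqrt(dim)

    def forward(self, x):  # x: (B, T, D)
        h = self.norm1(x)
        q, k, v = self.wq(h), self.wk(h), self.wv(h)
        attn = softmax((q @ k.transpose(0, 2, 1)) * self.scale, axis=-1)
        x = x + self.wo(attn @ v)
        h = self.norm2(x)
        return x + self.mlp2(self.act(self.mlp1(h)))


class _AttnWrapper(Module):
    """Exposes attention projections under an ``attn.*`` name prefix."""

    def __init__(self, block: _AttentionBlock):
        super().__init__()
        self.attn = block

    def forward(self, x):
        return self.attn(x)


class TinyViT(Module):
    """Minimal vision transformer: 8-px token patches, 2 blocks, mean-pool."""

    TOKEN_PX = 8

    def __init__(self, feature_dim: int, rng: np.random.Generator, input_px: int = 64):
        super().__init__()
        if input_px % self.TOKEN_PX != 0:
            raise ValueError(f"input_px must be a multiple of {self.TOKEN_PX}")
        self.input_px = input_px
        dim = 48
        n_tok = (input_px // self.TOKEN_PX) ** 2
        self.embed = Linear(3 * self.TOKEN_PX**2, dim, rng)
        self.pos = Tensor(rng.normal(0.0, 0.02, size=(1, n_tok, dim)), requires_grad=True)
        self.block1 = _AttnWrapper(_AttentionBlock(dim, rng))
        self.block2 = _AttnWrapper(_AttentionBlock(dim, rng))
        self.norm = LayerNorm(dim)
        self.head = Linear(dim, feature_dim, rng)

    def forward(self, x):
        x = as_tensor(x)
        B, C, H, W = x.shape
        if H != self.input_px or W != self.input_px:
            logger.info("resizing %dx%d patches to %d for tiny_vit", H, W, self.input_px)
            x = Tensor(_resize_nchw(x.data, self.input_px))
        t = self.TOKEN_PX
        n = self.input_px // t
        # (B, C, n, t, n, t) -> (B, n*n, C*t*t)
        tok = x.reshape(B, C, n, t, n, t).transpose(0, 2, 4, 1, 3, 5).reshape(B, n * n, C * t * t)
        h = self.embed(tok) + self.pos
        h = self.block2(self.block1(h))
        return self.head(self.norm(h).mean(axis=1))


def _resize_nchw(x: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbor square resize of an (B, C, H, W) batch."""
    B, C, H, W = x.shape
    ri = np.clip(np.round(np.arange(side) * H / side).astype(int), 0, H - 1)
    ci = np.clip(np.round(np.arange(side) * W / side).astype(int), 0, W - 1)
    return x[:, :, ri[:, None], ci[None, :]]


def build_backbone(spec: BackboneSpec, rng: np.random.Generator) -> Module:
    if spec.name == "tiny_cnn":
        backbone = TinyCNN(spec.feature_dim, rng)
    elif spec.name == "tiny_vit":
        backbone = TinyViT(spec.feature_dim, rng, input_px=spec.input_px or 64)
    else:
        raise ValueError(
            f"backbone {spec.name!r} is not bundled; built-ins are 'tiny_cnn' and "
            "'tiny_vit'. External foundation models plug in by passing a Module "
            "to build_bundle(backbone_module=...).")
    return backbone


def make_snn(in_dim: int, hidden: int, depth: int, dropout: float,
             rng: np.random.Generator) -> Sequential:
    """Self-normalizing MLP: Linear(lecun) + SELU (+ alpha-dropout) blocks."""
    steps: list[Module] = []
    d = in_dim
    for _ in range(depth):
        steps.append(Linear(d, hidden, rng))
        steps.append(SELU())
        if dropout > 0:
            steps.append(AlphaDropout(dropout, rng))
        d = hidden
    return Sequential(*steps)


# ------------------------------------------------------------------- bundle
@dataclass
class ModelBundle:
    """The four trainable components plus the metadata needed for inference."""

    backbone: Module
    morph_proj: Module
    molec_snn: Module
    molec_proj: Module
    abundance_head: Module
    expr_decoder: Module
    spec: BackboneSpec
    d_a: int
    r: int
    k: int
    snn_hidden: int = 256
    snn_depth: int = 2
    snn_dropout: float = 0.1
    gene_selection: GeneSelection | None = None
    celltype_names: list[str] | None = None
    norm_mode: str = "log1p_median"

    def modules(self) -> dict[str, Module]:
        return {"backbone": self.backbone, "morph_proj": self.morph_proj,
                "molec_snn": self.molec_snn, "molec_proj": self.molec_proj,
                "abundance_head": self.abundance_head, "expr_decoder": self.expr_decoder}

    def morph_parameters(self) -> list[Tensor]:
        return self.backbone.parameters() + self.morph_proj.parameters()

    def trainable_parameters(self) -> list[Tensor]:
        out = []
        for m in self.modules().values():
            out.extend(m.trainable_parameters())
        return out

    def train(self):
        for m in self.modules().values():
            m.train()
        return self

    def eval(self):
        for m in self.modules().values():
            m.eval()
        return self


def build_bundle(spec: BackboneSpec, d_a: int = 256, r: int = 250, k: int = 8,
                 seed: int = 0, snn_hidden: int = 256, snn_depth: int = 2,
                 snn_dropout: float = 0.1, backbone_module: Module | None = None,
                 celltype_names: list[str] | None = None) -> ModelBundle:
    """Construct all components with a single seed governing initialization."""
    rng = np.random.default_rng(seed)
    backbone = backbone_module if backbone_module is not None else build_backbone(spec, rng)
    if spec.lora is not None:
        targets = spec.lora.target_layers
        if targets == "auto":
            targets = spec.default_lora_targets()
        n = lora_wrap(backbone, targets, rank=spec.lora.rank, alpha=spec.lora.alpha,
                      rng=rng, dropout=spec.lora.dropout)
        logger.info("LoRA-wrapped %d layers matching %r", n, targets)
    elif spec.frozen:
        for p in backbone.parameters():
            p.requires_grad = False
    morph_proj = Sequential(Linear(spec.feature_dim, 512, rng), SELU(),
                            Linear(512, d_a, rng))
    molec_snn = make_snn(r, snn_hidden, snn_depth, snn_dropout, rng)
    molec_proj = Sequential(Linear(snn_hidden, 512, rng), SELU(), Linear(512, d_a, rng))
    abundance_head = Sequential(Linear(d_a, 256, rng), SELU(), Linear(256, k, rng))
    expr_decoder = Sequential(Linear(d_a, 256, rng), SELU(), Linear(256, r, rng))
    return ModelBundle(backbone=backbone, morph_proj=morph_proj, molec_snn=molec_snn,
                       molec_proj=molec_proj, abundance_head=abundance_head,
                       expr_decoder=expr_decoder, spec=spec, d_a=d_a, r=r, k=k,
                       snn_hidden=snn_hidden, snn_depth=snn_depth, snn_dropout=snn_dropout,
                       celltype_names=celltype_names)


# ---------------------------------------------------------------- operations
def morph_embed(bundle: ModelBundle, patches) -> Tensor:
    """g = P(T(p)): morphology embeddings, (B, d_a)."""
    x = as_tensor(np.asarray(patches, dtype=np.float64)
                  if not isinstance(patches, Tensor) else patches)
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError(f"patches must be (B, 3, H, W), got {x.shape}")
    return bundle.morph_proj(bundle.backbone(x))


def molec_embed(bundle: ModelBundle, h) -> Tensor:
    """s = H(S(h)): molecule embeddings from the top-r gene vector, (B, d_a)."""
    h = as_tensor(h)
    if h.ndim != 2 or h.shape[1] != bundle.r:
        raise ValueError(f"expression input must be (B, r={bundle.r}), got {h.shape}")
    return bundle.molec_proj(bundle.molec_snn(h))


def predict_abundance(bundle: ModelBundle, g) -> Tensor:
    """y_hat = A(g): unconstrained abundance regression output, (B, k)."""
    g = as_tensor(g)
    if g.ndim != 2 or g.shape[1] != bundle.d_a:
        raise ValueError(f"embeddings must be (B, d_a={bundle.d_a}), got {g.shape}")
    return bundle.abundance_head(g)


def reconstruct_expression(bundle: ModelBundle, s) -> Tensor:
    """h_hat = G(s): reconstructed top-r expression, (B, r)."""
    s = as_tensor(s)
    if s.ndim != 2 or s.shape[1] != bundle.d_a:
        raise ValueError(f"embeddings must be (B, d_a={bundle.d_a}), got {s.shape}")
    return bundle.expr_decoder(s)


# -------------------------------------------------------------- checkpointing
def save_checkpoint(bundle: ModelBundle, path) -> None:
    arrays: dict[str, np.ndarray] = {}
    for mod_name, mod in bundle.modules().items():
        for k, v in mod.state_dict().items():
            arrays[f"{mod_name}.{k}"] = v
    trainable = {f"{mod_name}.{k}": p.requires_grad
                 for mod_name, mod in bundle.modules().items()
                 for k, p in mod.named_parameters().items()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "spec": {**asdict(bundle.spec), "lora": asdict(bundle.spec.lora) if bundle.spec.lora else None},
        "d_a": bundle.d_a, "r": bundle.r, "k": bundle.k,
        "snn_hidden": bundle.snn_hidden, "snn_depth": bundle.snn_depth,
        "snn_dropout": bundle.snn_dropout,
        "gene_selection": (None if bundle.gene_selection is None else
                           {"indices": list(bundle.gene_selection.indices),
                            "criterion": bundle.gene_selection.criterion,
                            "r": bundle.gene_selection.r}),
        "celltype_names": bundle.celltype_names,
        "norm_mode": bundle.norm_mode,
        "trainable": trainable,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ModelBundle:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    spec_d = dict(meta["spec"])
    lora_d = spec_d.pop("lora", None)
    spec = BackboneSpec(**spec_d, lora=LoRAConfig(**lora_d) if lora_d else None)
    gs = meta["gene_selection"]
    bundle = build_bundle(spec, d_a=meta["d_a"], r=meta["r"], k=meta["k"], seed=0,
                          snn_hidden=meta["snn_hidden"], snn_depth=meta["snn_depth"],
                          snn_dropout=meta["snn_dropout"],
                          celltype_names=meta["celltype_names"])
    bundle.gene_selection = (GeneSelection(indices=tuple(gs["indices"]),
                                           criterion=gs["criterion"], r=gs["r"])
                             if gs else None)
    bundle.norm_mode = meta.get("norm_mode", "log1p_median")
    for mod_name, mod in bundle.modules().items():
        state = {k[len(mod_name) + 1:]: v for k, v in arrays.items()
                 if k.startswith(mod_name + ".")}
        mod.load_state_dict(state)
        for k, p in mod.named_parameters().items():
            p.requires_grad = meta["trainable"].get(f"{mod_name}.{k}", p.requires_grad)
    return bundle
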