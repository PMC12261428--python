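"""Low-rank adaptation (LoRA) for Linear layers.

A wrapped layer computes ``x @ (W + (alpha/rank) * A @ B) + bias`` where W and
bias are frozen and only the low-rank factors A (in_features x rank) and
B (rank x out_features) train.  B starts at zero, so a freshly wrapped layer
is bit-identical to the original — adapters change nothing until trained.
"""

from __future__ import annotations

import fnmatch

import numpy as np

from .layers import Linear, Module
from .tensor import Tensor, as_tensor


class LoRALinear(Module):
    def __init__(self, base: Linear, rank: int, alpha: float, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        d_in, d_out = base.in_features, base.out_features
        if rank > min(d_in, d_out):
            raise ValueError(f"LoRA rank {rank} exceeds min layer dim {min(d_in, d_out)}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("LoRA dropout must be in [0, 1)")
        self.in_features, self.out_features = d_in, d_out
        self.weight = Tensor(base.weight.data.copy(), requires_grad=False)
        self.bias = Tensor(base.bias.data.copy(), requires_grad=False)
        self.lora_a = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, rank)),
                             requires_grad=True)
        self.lora_b = Tensor(np.zeros((rank, d_out)), requires_grad=True)
        self.scaling = alpha / rank
        self.rank = rank
        self.dropout = dropout
        self._rng = rng

    def forward(self, x):
        x = as_tensor(x)
        base = x @ self.weight + self.bias
        xd = x
        if self.training and self.dropout > 0.0:
            keep = (self._rng.random(x.shape) >= self.dropout) / (1.0 - self.dropout)
            xd = x * Tensor(keep)
        return base + (xd @ self.lora_a @ self.lora_b) * self.scaling

    def trainable_count(self) -> int:
        return self.rank * (self.in_features + self.out_features)


def lora_wrap(module: Module, target_layers: str, rank: int, alpha: float,
              rng: np.random.Generator, dropout: float = 0.0) -> int:
    """Replace every Linear whose qualified name matches ``target_layers``
    (fnmatch pattern, e.g. ``"*attn.wq"`` or ``"head"``) with a LoRA-adapted
    copy, and freeze all remaining parameters of ``module``.

    Returns the number of layers wrapped; raises if the selector matches none.
    """
    matches: list[tuple[Module, str, Linear]] = []

    def visit(mod: Module, prefix: str):
        for name, child in list(mod._modules.items()):
            qual = prefix + name if not prefix else f"{prefix}.{name}"
            if isinstance(child, Linear) and fnmatch.fnmatch(qual, target_layers):
                matches.append((mod, name, child))
            else:
                visit(child, qual)

    visit(module, "")
    if not matches:
        raise ValueError(f"LoRA selector {target_layers!r} matched no Linear layers")
    for p in module.parameters():
        p.requires_grad = False
    for parent, name, base in matches:
        wrapped = LoRALinear(base, rank=rank, alpha=alpha, rng=rng, dropout=dropout)
        setattr(parent, name, wrapped)
        # keep Sequential step lists consistent
        if hasattr(parent, "steps"):
            parent.steps = [wrapped if s is base else s for s in parent.steps]
    return len(matches)
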