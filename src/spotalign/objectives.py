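"""Training objectives: cross-modal alignment, abundance regression,
expression reconstruction, and their weighted sum.

All three primary terms share one RMSE convention — the square root of the
mean squared residual over **all scalar elements** of the batch
(``sqrt(mean((x - y)^2))`` over B x dim entries).  This keeps loss magnitudes
comparable across embedding width, cell-type count and gene count, so one set
of weights behaves consistently.  Alignment-loss alternatives (plain MSE, a
symmetric KL divergence on row-softmaxed embeddings, and a symmetric infoNCE
contrastive loss) are selectable for ablation.

Every loss accepts numpy arrays or autograd tensors and returns an autograd
Tensor, so the same code path serves evaluation and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnx import Tensor, as_tensor, log_softmax, softmax

ALIGNMENT_VARIANTS = ("rmse", "mse", "kld", "infonce")


@dataclass(frozen=True)
class LossWeights:
    lambda_C: float = 1.0   # alignment
    lambda_A: float = 1.0   # abundance regression
    lambda_G: float = 1.0   # expression reconstruction

    def __post_init__(self):
        if min(self.lambda_C, self.lambda_A, self.lambda_G) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_C == self.lambda_A == self.lambda_G == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class LossReport:
    total: float
    align: float
    abundance: float
    reconstruction: float
    align_variant: str = "rmse"

    def as_dict(self) -> dict:
        return {"total": self.total, "align": self.align, "abundance": self.abundance,
                "reconstruction": self.reconstruction, "align_variant": self.align_variant}


def _check_pair(a, b, what: str):
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] == 0:
        raise ValueError(f"{what}: expected nonempty (B, dim) matrices, got {a.shape}")
    return a, b


def _rmse(a: Tensor, b: Tensor) -> Tensor:
    # exact sqrt(mean of squared residuals); the gradient is undefined at a
    # perfectly matched pair, which does not arise during optimization
    diff = a - b
    return ((diff * diff).mean()) ** 0.5


def alignment_loss(g, s, variant: str = "rmse", temperature: float = 0.07) -> Tensor:
    """Cross-modal consistency loss between paired morphology embeddings ``g``
    and molecule embeddings ``s`` (both B x d_a)."""
    g, s = _check_pair(g, s, "alignment_loss")
    if variant == "rmse":
        return _rmse(g, s)
    if variant == "mse":
        diff = g - s
        return (diff * diff).mean()
    if variant == "kld":
        # symmetric KL between row-softmaxed embeddings, mean over the batch
        lp, lq = log_softmax(g, axis=-1), log_softmax(s, axis=-1)
        p, q = softmax(g, axis=-1), softmax(s, axis=-1)
        kl_pq = (p * (lp - lq)).sum(axis=-1)
        kl_qp = (q * (lq - lp)).sum(axis=-1)
        return 0.5 * (kl_pq + kl_qp).mean()
    if variant == "infonce":
        gn = g * ((g * g).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
        sn = s * ((s * s).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
        logits = (gn @ sn.T) * (1.0 / temperature)
        B = logits.shape[0]
        diag = (np.arange(B), np.arange(B))
        loss_g = -(log_softmax(logits, axis=-1)[diag]).mean()
        loss_s = -(log_softmax(logits.T, axis=-1)[diag]).mean()
        return 0.5 * (loss_g + loss_s)
    raise ValueError(f"unknown alignment variant {variant!r}; "
                     f"choose from {ALIGNMENT_VARIANTS}")


def abundance_loss(y, y_hat) -> Tensor:
    """RMSE between true and predicted cell-type abundances (B x k)."""
    y, y_hat = _check_pair(y, y_hat, "abundance_loss")
    return _rmse(y, y_hat)


def reconstruction_loss(h, h_hat) -> Tensor:
    """RMSE between input and reconstructed top-gene expression (B x r)."""
    h, h_hat = _check_pair(h, h_hat, "reconstruction_loss")
    return _rmse(h, h_hat)


def total_loss(align: Tensor, abundance: Tensor, reconstruction: Tensor,
               weights: LossWeights, align_variant: str = "rmse") -> tuple[Tensor, LossReport]:
    """Weighted sum of the three terms.  L2 regularization is applied through
    the optimizer's decoupled weight decay, not inside this scalar.

    Returns the differentiable total plus a float report of all components.
    """
    align, abundance, reconstruction = (as_tensor(align), as_tensor(abundance),
                                        as_tensor(reconstruction))
    total = (weights.lambda_C * align + weights.lambda_A * abundance
             + weights.lambda_G * reconstruction)
    report = LossReport(total=total.item(), align=align.item(), abundance=abundance.item(),
                        reconstruction=reconstruction.item(), align_variant=align_variant)
    return total, report
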