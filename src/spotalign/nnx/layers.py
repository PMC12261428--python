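"""Neural-network layers on top of the numpy autograd tape.

Initialization defaults follow the self-normalizing-network recipe
(lecun-normal: std = 1/sqrt(fan_in), zero bias) so that deep SELU stacks
preserve activation moments at initialization.
"""

from __future__ import annotations

import numpy as np

from .tensor import SELU_ALPHA, SELU_SCALE, Tensor, as_tensor, conv2d


class Module:
    """Base class: tracks child modules and parameters by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        object.__setattr__(self, key, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {}
        for k, p in self._params.items():
            out[prefix + k] = p
        for k, m in self._modules.items():
            out.update(m.named_parameters(prefix + k + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init: str = "lecun"):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        if init == "lecun":
            std = 1.0 / np.sqrt(in_features)
            w = rng.normal(0.0, std, size=(in_features, out_features))
        elif init == "xavier":
            lim = np.sqrt(6.0 / (in_features + out_features))
            w = rng.uniform(-lim, lim, size=(in_features, out_features))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x) @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(as_tensor(x), self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class SELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x).selu()


class AlphaDropout(Module):
    """Dropout variant that preserves the SELU self-normalizing fixed point.

    Dropped units are set to the SELU negative saturation value -scale*alpha,
    then an affine correction restores zero mean / unit variance in
    expectation.  Identity in eval mode.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng
        ap = -SELU_SCALE * SELU_ALPHA  # alpha' (saturation value)
        q = 1.0 - p
        self._a = (q + ap**2 * q * p) ** -0.5
        self._b = -self._a * p * ap
        self._ap = ap

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if not self.training or self.p == 0.0:
            return x
        keep = Tensor((self.rng.random(x.shape) >= self.p).astype(np.float64))
        return (x * keep + self._ap * (1.0 - keep)) * self._a + self._b


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"step{i}", m)

    def forward(self, x):
        for m in self.steps:
            x = m(x)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class GlobalAvgPool2d(Module):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x).mean(axis=(2, 3))
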