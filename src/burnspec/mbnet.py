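"""Dual-branch bidirectional Mamba network for spectral classification.

A reflectance curve is treated as a sequence over the band axis
(ascending wavelength). Each scalar band value is embedded into a
``model_dim``-wide feature ("dimensional padding"), then two independent
Mamba branches scan the band sequence — one in ascending ("sequential")
and one in descending ("reverse") wavelength order, the reverse branch
flipping its output back so band positions align. Each branch pools the
channel axis back to a per-band feature, applies BatchNorm over band
positions and LeakyReLU, and the two branch outputs are fused by
elementwise addition. A two-layer head compresses the fused D-band
feature to 100 hidden units and then to the class count (6 burn
temperatures by default).

Ablation variants: ``sequential_only`` / ``reverse_only`` keep a single
branch (no fusion term); ``no_mamba`` replaces the Mamba blocks with the
identity in both branches, reducing the network to an MLP-like
pad -> pool -> BatchNorm -> LeakyReLU -> head pipeline.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor
from .ssm_core import MambaBlock, MambaBlockParameters

__all__ = ["MBNet", "BatchNorm1d", "fuse", "VARIANTS"]

VARIANTS = ("bidirectional", "sequential_only", "reverse_only", "no_mamba")


class BatchNorm1d:
    """Batch normalization over the last axis of a [B, F] feature array.

    Training mode normalizes with the batch mean/variance (requires B >= 2)
    and updates running statistics; eval mode uses the running statistics.
    Running statistics are seeded from the first batch and then tracked
    with exponential momentum 0.1, so eval-mode behavior follows
    train-mode behavior from the first step even when feature variances
    are far from 1, while still forgetting early-training drift. eps 1e-5.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.num_batches = 0
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training:
            scale = self.gamma * (1.0 / np.sqrt(self.running_var + self.eps))
            return (x - self.running_mean) * scale + self.beta

        B = x.shape[0]
        if B < 2:
            raise ValueError("BatchNorm in training mode requires batch size >= 2")
        mu = x.data.mean(axis=0)
        var = x.data.var(axis=0)
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mu) / std
        gamma, beta = self.gamma, self.beta
        out = Tensor(gamma.data * xhat + beta.data, _prev=(x, gamma, beta))

        def _bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=0))
            if beta.requires_grad:
                beta._accum(g.sum(axis=0))
            if x.requires_grad:
                gx = (gamma.data / std) * (
                    g - g.mean(axis=0)
                    - xhat * (g * xhat).mean(axis=0))
                x._accum(gx)

        out._backward = _bw

        n = self.num_batches
        unbiased = var * (B / max(B - 1, 1))
        # cumulative averaging until it decays to the exponential rate
        w = 1.0 if n == 0 else max(self.momentum, 1.0 / (n + 1))
        self.running_mean = ((1 - w) * self.running_mean
                             + w * mu.astype(self.running_mean.dtype))
        self.running_var = ((1 - w) * self.running_var
                            + w * unbiased.astype(self.running_var.dtype))
        self.num_batches = n + 1
        return out

    def tensors(self) -> list[Parameter]:
        return [self.gamma, self.beta]


def fuse(a, b):
    """Elementwise additive fusion of the two directional branch outputs."""
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if tuple(sa) != tuple(sb):
        raise ValueError(f"branch outputs must have identical shapes, got {sa} vs {sb}")
    return a + b


class _Branch:
    """One scan direction: Mamba block stack (with residual), channel
    pooling, BatchNorm over band positions, LeakyReLU."""

    def __init__(self, n_bands, model_dim, state_dim, expand, conv_width,
                 depth, leaky_slope, rng, dtype):
        self.blocks = [
            MambaBlock(MambaBlockParameters.init(
                model_dim, state_dim=state_dim, expand=expand,
                conv_width=conv_width, rng=rng, dtype=dtype))
            for _ in range(depth)
        ]
        self.bn = BatchNorm1d(n_bands, dtype=dtype)
        self.leaky_slope = leaky_slope

    def __call__(self, x: Tensor, reverse: bool, training: bool,
                 use_mamba: bool = True) -> Tensor:
        z = x.flip(1) if reverse else x
        if use_mamba:
            for block in self.blocks:
                z = z + block(z)
        if reverse:
            z = z.flip(1)  # re-align band positions before fusion
        pooled = z.mean(axis=2)
        return self.bn(pooled, training).leaky_relu(self.leaky_slope)

    def tensors(self):
        out = []
        for b in self.blocks:
            out += b.tensors()
        return out + self.bn.tensors()


class MBNet:
    """The bidirectional spectral classification network.

    Parameters
    ----------
    n_bands : sequence length D (number of spectral bands; 260 for a
        400-1000 nm visible/NIR instrument).
    n_classes : output width C (6 burn-temperature classes by default).
    model_dim : per-band embedding width (the scan's channel count).
    state_dim, expand, conv_width, depth : Mamba block hyperparameters.
    hidden : width of the head's compression layer (100).
    leaky_slope : LeakyReLU negative slope (0.01).
    seed : initialization seed; fixed seed gives bit-identical weights.
    """

    def __init__(self, n_bands: int, n_classes: int = 6, model_dim: int = 16,
                 state_dim: int = 16, expand: int = 2, conv_width: int = 4,
                 depth: int = 1, hidden: int = 100, leaky_slope: float = 0.01,
                 seed: int = 0, dtype=np.float32):
        if n_bands < 1 or n_classes < 2:
            raise ValueError("need n_bands >= 1 and n_classes >= 2")
        rng = np.random.default_rng(seed)
        self.n_bands = n_bands
        self.n_classes = n_classes
        self.model_dim = model_dim
        self.leaky_slope = leaky_slope
        self.hidden = hidden
        self.config = dict(n_bands=n_bands, n_classes=n_classes,
                           model_dim=model_dim, state_dim=state_dim,
                           expand=expand, conv_width=conv_width, depth=depth,
                           hidden=hidden, leaky_slope=leaky_slope, seed=seed)

        bound_e = 1.0
        self.W_embed = Parameter(rng.uniform(-bound_e, bound_e, (1, model_dim)).astype(dtype))
        self.b_embed = Parameter(np.zeros(model_dim, dtype=dtype))
        self.branch_seq = _Branch(n_bands, model_dim, state_dim, expand,
                                  conv_width, depth, leaky_slope, rng, dtype)
        self.branch_rev = _Branch(n_bands, model_dim, state_dim, expand,
                                  conv_width, depth, leaky_slope, rng, dtype)
        bound1 = 1.0 / np.sqrt(n_bands)
        bound2 = 1.0 / np.sqrt(hidden)
        self.W_fc1 = Parameter(rng.uniform(-bound1, bound1, (n_bands, hidden)).astype(dtype))
        self.b_fc1 = Parameter(rng.uniform(-bound1, bound1, hidden).astype(dtype))
        self.W_fc2 = Parameter(rng.uniform(-bound2, bound2, (hidden, n_classes)).astype(dtype))
        self.b_fc2 = Parameter(rng.uniform(-bound2, bound2, n_classes).astype(dtype))

    # ---- stages ---------------------------------------------------------

    def pad_spectrum(self, Yin) -> Tensor:
        """Embed each scalar band value into a model_dim-wide feature,
        appending a channel axis; sequence length stays D."""
        x = Yin if isinstance(Yin, Tensor) else Tensor(np.asarray(Yin))
        if x.ndim != 2:
            raise ValueError("expected a [B, D] batch of spectra")
        if not np.all(np.isfinite(x.data)):
            raise ValueError("spectra contain non-finite values")
        B, D = x.shape
        if D != self.n_bands:
            raise ValueError(f"expected {self.n_bands} bands, got {D}")
        return x.reshape(B, D, 1) @ self.W_embed + self.b_embed

    def branch_forward(self, x: Tensor, direction: str, training: bool = False,
                       use_mamba: bool = True) -> Tensor:
        if direction == "sequential":
            return self.branch_seq(x, reverse=False, training=training, use_mamba=use_mamba)
        if direction == "reverse":
            return self.branch_rev(x, reverse=True, training=training, use_mamba=use_mamba)
        raise ValueError(f"unknown direction {direction!r}")

    def classify_head(self, Yout: Tensor, return_hidden: bool = False):
        Yout = Yout if isinstance(Yout, Tensor) else Tensor(np.asarray(Yout))
        if Yout.shape[-1] != self.n_bands:
            raise ValueError(f"head expects {self.n_bands}-wide features, got {Yout.shape[-1]}")
        hidden = (Yout @ self.W_fc1 + self.b_fc1).leaky_relu(self.leaky_slope)
        logits = hidden @ self.W_fc2 + self.b_fc2
        return (logits, hidden) if return_hidden else logits

    def forward(self, Yin, variant: str = "bidirectional",
                training: bool = False) -> Tensor:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose one of {VARIANTS}")
        x = self.pad_spectrum(Yin)
        use_mamba = variant != "no_mamba"
        if variant == "sequential_only":
            feat = self.branch_forward(x, "sequential", training)
        elif variant == "reverse_only":
            feat = self.branch_forward(x, "reverse", training)
        else:  # bidirectional / no_mamba keep both paths
            y_seq = self.branch_forward(x, "sequential", training, use_mamba)
            y_rev = self.branch_forward(x, "reverse", training, use_mamba)
            feat = fuse(y_seq, y_rev)
        return self.classify_head(feat)

    __call__ = forward

    def predict(self, Yin, variant: str = "bidirectional") -> np.ndarray:
        """Eval-mode class predictions for a [N, D] array of spectra."""
        return np.argmax(self.forward(Yin, variant=variant, training=False).data, axis=1)

    # ---- parameter plumbing --------------------------------------------

    def parameters(self) -> list[Parameter]:
        return ([self.W_embed, self.b_embed]
                + self.branch_seq.tensors() + self.branch_rev.tensors()
                + [self.W_fc1, self.b_fc1, self.W_fc2, self.b_fc2])

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable arrays plus BatchNorm running statistics, keyed by
        stable names — the payload of the checkpoint format."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i:03d}"] = p.data
        for name, br in (("seq", self.branch_seq), ("rev", self.branch_rev)):
            out[f"bn_{name}_mean"] = br.bn.running_mean
            out[f"bn_{name}_var"] = br.bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = arrays[f"param_{i:03d}"]
            if src.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for param_{i:03d}: "
                                 f"{src.shape} vs {p.data.shape}")
            p.data = src.astype(p.data.dtype)
        for name, br in (("seq", self.branch_seq), ("rev", self.branch_rev)):
            br.bn.running_mean = arrays[f"bn_{name}_mean"].copy()
            br.bn.running_var = arrays[f"bn_{name}_var"].copy()
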