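"""Multi-scale convolutional attention (MSCA) forward pass, pure numerics.

MSCA aggregates local context with a depthwise convolution, adds three
strip-convolution branches that approximate large 7x7, 11x11 and 21x21
kernels with separable 1xk / kx1 pairs, mixes channels with a 1x1
convolution, and applies the result as an elementwise gate:

    Att = Conv1x1( sum_{i=0..3} Scale_i( DW-Conv(F) ) )
    Out = Att * F          (elementwise)

where Scale_0 is a skip connection (the aggregated map itself). The
companion MSCAN encoder downsamples with stride-2 3x3 convolutions
followed by batch normalization. Everything here is inference-only
numerics on (channel, row, col) arrays; reflection padding keeps
spatial sizes and avoids dark borders that would produce spurious
attention at image edges. No nonlinearity is applied between branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "MscaWeights",
    "BnStats",
    "depthwise_conv",
    "strip_branch",
    "msca_forward",
    "mscan_downsample",
    "mscan_stage",
    "random_weights",
    "random_bn_stats",
    "save_weights",
    "load_weights",
]

DEFAULT_SCALES = (7, 11, 21)


@dataclass
class MscaWeights:
    """MSCA block weights.

    dw_kernel: (C, kh, kw) per-channel aggregation kernel (default 5x5);
    branch_kernels: {k: (u, v)} with u shaped (C, k) for the 1xk pass and
    v shaped (C, k) for the kx1 pass; mix_1x1: (C, C) channel mixer.
    """

    dw_kernel: np.ndarray
    branch_kernels: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    mix_1x1: np.ndarray = None  # type: ignore[assignment]

    def validate(self, channels: int) -> None:
        if self.dw_kernel.shape[0] != channels:
            raise ValueError(
                f"dw_kernel has {self.dw_kernel.shape[0]} channels, feature map has {channels}"
            )
        if self.dw_kernel.shape[1] % 2 == 0 or self.dw_kernel.shape[2] % 2 == 0:
            raise ValueError("dw_kernel spatial dims must be odd")
        for k, (u, v) in self.branch_kernels.items():
            if k % 2 == 0:
                raise ValueError(f"strip scale {k} must be odd")
            if u.shape != (channels, k) or v.shape != (channels, k):
                raise ValueError(f"branch {k} kernels must be shaped ({channels}, {k})")
        if self.mix_1x1.shape != (channels, channels):
            raise ValueError(
                f"mix_1x1 must be square ({channels}, {channels}) for the gating product, "
                f"got {self.mix_1x1.shape}"
            )


@dataclass
class BnStats:
    """Per-channel batch-norm statistics and affine parameters."""

    mean: np.ndarray
    var: np.ndarray
    gain: np.ndarray
    bias: np.ndarray
    epsilon: float = 1e-5

    def validate(self, channels: int) -> None:
        for name, arr in (("mean", self.mean), ("var", self.var), ("gain", self.gain), ("bias", self.bias)):
            if np.asarray(arr).shape != (channels,):
                raise ValueError(f"bn {name} must have shape ({channels},)")
        if (np.asarray(self.var) < 0).any():
            raise ValueError("bn variance must be non-negative")


def _as_chw(f: np.ndarray) -> np.ndarray:
    arr = np.asarray(f, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("feature map contains non-finite values")
    return arr


def depthwise_conv(f: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Per-channel 2-D convolution with reflection padding; shape preserved."""
    arr = _as_chw(f)
    k = np.asarray(kernels, dtype=float)
    if k.ndim != 3 or k.shape[0] != arr.shape[0]:
        raise ValueError(
            f"need one kernel per channel: kernels {k.shape} vs {arr.shape[0]} channels"
        )
    if k.shape[1] % 2 == 0 or k.shape[2] % 2 == 0:
        raise ValueError("kernels must be odd-sized")
    out = np.empty_like(arr)
    for c in range(arr.shape[0]):
        out[c] = ndimage.correlate(arr[c], k[c], mode="reflect")
    return out


def strip_branch(f: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Separable strip convolution: 1xk (row-wise, kernel u) then kx1
    (column-wise, kernel v), per channel. Equivalent to a dense depthwise
    k x k kernel v^T u."""
    arr = _as_chw(f)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.ndim != 2 or v.ndim != 2 or u.shape[0] != arr.shape[0] or v.shape[0] != arr.shape[0]:
        raise ValueError("strip kernels must be (C, k) with C matching the feature map")
    if u.shape[1] % 2 == 0 or v.shape[1] % 2 == 0:
        raise ValueError(f"strip scale must be odd, got {u.shape[1]} / {v.shape[1]}")
    horiz = depthwise_conv(arr, u[:, None, :])
    return depthwise_conv(horiz, v[:, :, None])


def msca_forward(f: np.ndarray, weights: MscaWeights) -> np.ndarray:
    """MSCA block: aggregate, branch, mix, gate.

    base = DW-Conv(F); Att = mix_1x1(base + sum_k strip_k(base));
    Out = Att * F elementwise. Linear in F up to the final gate, so the
    whole map is homogeneous of degree 2.
    """
    arr = _as_chw(f)
    weights.validate(arr.shape[0])
    base = depthwise_conv(arr, weights.dw_kernel)
    acc = base.copy()  # branch 0: skip connection
    for _, (u, v) in sorted(weights.branch_kernels.items()):
        acc += strip_branch(base, u, v)
    att = np.einsum("oc,chw->ohw", np.asarray(weights.mix_1x1, dtype=float), acc)
    return att * arr


def mscan_downsample(f: np.ndarray, conv_weights: np.ndarray, bn: BnStats) -> np.ndarray:
    """Stride-2 3x3 convolution (reflection padding 1) followed by
    batch normalization; output spatial dims are ceil(H/2) x ceil(W/2)."""
    arr = _as_chw(f)
    w = np.asarray(conv_weights, dtype=float)
    if w.ndim != 4 or w.shape[1] != arr.shape[0] or w.shape[2:] != (3, 3):
        raise ValueError(
            f"conv weights must be (C_out, C_in={arr.shape[0]}, 3, 3), got {w.shape}"
        )
    c_out = w.shape[0]
    bn.validate(c_out)
    _, h, wd = arr.shape
    # np.pad "symmetric" matches ndimage's reflect (edge value repeated)
    padded = np.pad(arr, ((0, 0), (1, 1), (1, 1)), mode="symmetric")
    h_out = -(-h // 2)
    w_out = -(-wd // 2)
    out = np.zeros((c_out, h_out, w_out))
    for i in range(h_out):
        for j in range(w_out):
            window = padded[:, 2 * i : 2 * i + 3, 2 * j : 2 * j + 3]
            out[:, i, j] = np.einsum("oikl,ikl->o", w, window)
    mean = np.asarray(bn.mean, dtype=float)[:, None, None]
    var = np.asarray(bn.var, dtype=float)[:, None, None]
    gain = np.asarray(bn.gain, dtype=float)[:, None, None]
    bias = np.asarray(bn.bias, dtype=float)[:, None, None]
    return (out - mean) / np.sqrt(var + bn.epsilon) * gain + bias


def mscan_stage(
    f: np.ndarray,
    conv_weights: np.ndarray,
    bn: BnStats,
    msca_blocks: list[MscaWeights],
) -> np.ndarray:
    """One encoder stage: downsample once, then a stack of MSCA blocks."""
    out = mscan_downsample(f, conv_weights, bn)
    for w in msca_blocks:
        out = msca_forward(out, w)
    return out


# ---------------------------------------------------------------------------
# Deterministic weights for testing, and archive I/O
# ---------------------------------------------------------------------------

def random_weights(
    channels: int,
    seed: int,
    dw_size: int = 5,
    scales: tuple[int, ...] = DEFAULT_SCALES,
) -> MscaWeights:
    """Deterministic random MSCA weights (standard normal / sqrt fan-in)."""
    rng = np.random.default_rng(seed)
    dw = rng.standard_normal((channels, dw_size, dw_size)) / dw_size
    branches = {
        k: (
            rng.standard_normal((channels, k)) / np.sqrt(k),
            rng.standard_normal((channels, k)) / np.sqrt(k),
        )
        for k in scales
    }
    mix = rng.standard_normal((channels, channels)) / np.sqrt(channels)
    return MscaWeights(dw_kernel=dw, branch_kernels=branches, mix_1x1=mix)


def random_bn_stats(channels: int, seed: int) -> BnStats:
    rng = np.random.default_rng(seed)
    return BnStats(
        mean=rng.standard_normal(channels) * 0.1,
        var=rng.uniform(0.5, 1.5, channels),
        gain=rng.uniform(0.8, 1.2, channels),
        bias=rng.standard_normal(channels) * 0.1,
    )


def save_weights(weights: MscaWeights, path: str | Path) -> None:
    """Store all arrays in one compressed .npz archive."""
    arrays = {"dw_kernel": weights.dw_kernel, "mix_1x1": weights.mix_1x1}
    for k, (u, v) in weights.branch_kernels.items():
        arrays[f"branch_{k}_u"] = u
        arrays[f"branch_{k}_v"] = v
    np.savez_compressed(path, **arrays)


def load_weights(path: str | Path) -> MscaWeights:
    with np.load(path) as data:
        branches: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for name in data.files:
            if name.startswith("branch_") and name.endswith("_u"):
                k = int(name.split("_")[1])
                branches[k] = (data[name], data[f"branch_{k}_v"])
        return MscaWeights(
            dw_kernel=data["dw_kernel"], branch_kernels=branches, mix_1x1=data["mix_1x1"]
        )
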