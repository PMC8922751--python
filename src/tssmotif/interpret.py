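"""Kernel interpretation: N-adjusted PWM transformation, N-effect ranks,
and DeepLIFT-style attribution.

The N-adjusted transformation treats the cryptic-nucleotide (N) channel
of a trained first-layer kernel as a bias control: whatever weight the
N channel carries is attributed to model initialization and training
rather than sequence preference, so each nucleotide weight is measured
relative to it. For kernel entries O[i, j] (rows A, T, C, G, N):

    a[i, j] = max(0, O[i, j] - O[4, j])          i in {A, T, C, G}
    R[i, j] = a[i, j] / sum_i a[i, j]            if the sum is positive
    R[i, j] = 0.25                               if all four a[i, j] = 0

The fallback encodes "no nucleotide preference at this position". The
transform is invariant to adding a constant to a whole kernel column,
which is exactly the bias it is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KernelMatrix, Pwm

TSS_OFFSET = 500
TSS_MASK_HALF_WIDTH = 10


def n_adjusted_transform(kernel: KernelMatrix, name: str | None = None) -> Pwm:
    """Transform a 5 x L kernel into a column-stochastic 4 x L PWM,
    using the N row as the per-column bias control (dropped from the
    output)."""
    O = kernel.matrix
    if not np.all(np.isfinite(O)):
        raise ValueError("kernel contains non-finite entries")
    adjusted = np.maximum(0.0, O[:4] - O[4])
    colsums = adjusted.sum(axis=0)
    R = np.full_like(adjusted, 0.25)
    positive = colsums > 0
    R[:, positive] = adjusted[:, positive] / colsums[positive]
    if name is None:
        name = f"kernel_s{kernel.stage}_f{kernel.fold}_k{kernel.kernel_index}"
    return Pwm(
        R,
        name=name,
        provenance={
            "stage": kernel.stage,
            "fold": kernel.fold,
            "kernel_index": kernel.kernel_index,
        },
    )


def n_effect_ranks(kernel: KernelMatrix) -> np.ndarray:
    """Per-column rank of the N entry among the five channels.

    Ascending ranks starting at 0: rank 4 means N has the largest
    effect at that position, rank 0 the smallest. Ties give N the
    lowest rank among the tied values (counting only entries strictly
    below N), which deliberately under-states N's effect.
    """
    O = kernel.matrix
    return (O[:4] < O[4]).sum(axis=0).astype(np.int64)


# -------------------------------------------------------- attribution


@dataclass
class AttributionMatrix:
    """Per-position x per-channel effect scores (positive = pushes
    toward the expressed class)."""

    values: np.ndarray  # (length, 5) class average, or (n, length, 5)
    reference: str
    averaged: bool

    def tss_split(
        self, tss: int = TSS_OFFSET, half_width: int = TSS_MASK_HALF_WIDTH
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Split positions into (outside, inside) the TSS +/- 10 block;
        returns (outside values, inside values, inside position index)."""
        if not self.averaged:
            raise ValueError("split applies to the class-averaged matrix")
        pos = np.arange(self.values.shape[0])
        inside = (pos >= tss - half_width) & (pos <= tss + half_width)
        return self.values[~inside], self.values[inside], pos[inside]


def _relu_multiplier(dx: np.ndarray, x: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Rescale-rule multiplier for ReLU: delta(out)/delta(in), falling
    back to the local derivative where the input delta vanishes."""
    out = np.where(x > 0, 1.0, 0.0)
    nz = np.abs(dx) > eps
    delta_out = np.maximum(x, 0.0) - np.maximum(x - dx, 0.0)
    out = np.where(nz, np.divide(delta_out, dx, out=np.zeros_like(dx), where=nz), out)
    return out


def deeplift_attributions(
    model, X: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Per-gene attribution maps for the expressed-vs-low logit
    difference, by the rescale rule on the conv/ReLU/pool/dense stack.

    The attribution target is f = z[expressed] - z[low] (pre-softmax).
    Linear layers propagate multipliers exactly; ReLUs use the rescale
    rule; max-pool routes each block's output delta onto one input
    position with non-vanishing delta, so summation-to-delta holds
    exactly: sum of attributions = f(input) - f(reference).

    The default reference is the all-zeros one-hot ("no letter
    present"); any array broadcastable to X may be supplied instead.
    """
    X = np.asarray(X, dtype=np.float64)
    if reference is None:
        ref = np.zeros_like(X)
    else:
        ref = np.broadcast_to(np.asarray(reference, dtype=np.float64), X.shape).copy()

    p = {k: v.astype(np.float64) for k, v in model.params.items()}
    n = X.shape[0]
    F, pw = model.cfg.n_filters, model.cfg.pool_width
    nb = model.n_blocks

    def fwd(inp):
        fwin = model._conv_windows(inp.astype(np.float32)).astype(np.float64)
        zc = fwin @ p["Wc"] + p["bc"]
        ac = np.maximum(zc, 0.0)
        trimmed = ac[:, : nb * pw].reshape(n, nb, pw, F)
        pooled = trimmed.max(axis=2)
        flat = pooled.reshape(n, -1)
        z1 = flat @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        return fwin, zc, trimmed, pooled, flat, z1, a1, z2

    fwin_x, zc_x, trim_x, pool_x, flat_x, z1_x, a1_x, z2_x = fwd(X)
    fwin_r, zc_r, trim_r, pool_r, flat_r, z1_r, a1_r, z2_r = fwd(ref)

    # target: expressed minus low logit; multipliers flow backward
    w_target = p["W2"][:, 1] - p["W2"][:, 0]  # (D,)
    m_a1 = np.broadcast_to(w_target, a1_x.shape).copy()
    m_z1 = m_a1 * _relu_multiplier(z1_x - z1_r, z1_x)
    m_flat = m_z1 @ p["W1"].T
    m_pool = m_flat.reshape(n, nb, F)

    # max-pool: route the block's delta to one input with nonzero delta
    d_trim = trim_x - trim_r
    d_pool = pool_x - pool_r
    m_trim = np.zeros_like(trim_x)
    # choose the in-block position with the largest |delta|
    route = np.abs(d_trim).argmax(axis=2)  # (n, nb, F)
    d_at_route = np.take_along_axis(d_trim, route[:, :, None, :], axis=2)[:, :, 0]
    safe = np.abs(d_at_route) > 1e-12
    ratio = np.divide(
        d_pool, d_at_route, out=np.zeros_like(d_pool), where=safe
    )
    np.put_along_axis(
        m_trim, route[:, :, None, :], (m_pool * ratio)[:, :, None, :], axis=2
    )
    m_ac = np.zeros_like(zc_x)
    m_ac[:, : nb * pw] = m_trim.reshape(n, nb * pw, F)

    m_zc = m_ac * _relu_multiplier(zc_x - zc_r, zc_x)
    m_fwin = m_zc @ p["Wc"].T  # (n, conv_out, L*5)

    # scatter conv-window multipliers back onto input positions
    L = model.cfg.kernel_width
    m_X = np.zeros_like(X)
    m_fwin_r = m_fwin.reshape(n, model.conv_out, L, 5)
    for t in range(L):
        m_X[:, t : t + model.conv_out] += m_fwin_r[:, :, t]
    return m_X * (X - ref)


def attribution(
    model,
    windows: np.ndarray,
    gene_ids: list[str] | None = None,
    reference: np.ndarray | None = None,
) -> AttributionMatrix:
    """Class-averaged attribution over true-positive windows, with the
    TSS +/- 10 split available via ``tss_split``."""
    windows = np.asarray(windows)
    if windows.ndim == 2:
        windows = windows[None]
    if windows.shape[0] == 0:
        raise ValueError("empty true-positive set: nothing to interpret")
    per_gene = deeplift_attributions(model, windows, reference)
    ref_desc = "zeros" if reference is None else "custom"
    return AttributionMatrix(
        values=per_gene.mean(axis=0), reference=ref_desc, averaged=True
    )


def gradient_x_input(model, X: np.ndarray) -> np.ndarray:
    """Gradient-times-input fallback attribution (labeled as such in
    outputs); same target as ``deeplift_attributions``."""
    X = np.asarray(X, dtype=np.float64)
    p = {k: v.astype(np.float64) for k, v in model.params.items()}
    n = X.shape[0]
    F, pw, nb = model.cfg.n_filters, model.cfg.pool_width, model.n_blocks
    fwin = model._conv_windows(X.astype(np.float32)).astype(np.float64)
    zc = fwin @ p["Wc"] + p["bc"]
    ac = np.maximum(zc, 0.0)
    trimmed = ac[:, : nb * pw].reshape(n, nb, pw, F)
    arg = trimmed.argmax(axis=2)
    pooled = np.take_along_axis(trimmed, arg[:, :, None], axis=2)[:, :, 0]
    flat = pooled.reshape(n, -1)
    z1 = flat @ p["W1"] + p["b1"]
    a1 = np.maximum(z1, 0.0)

    g_a1 = np.broadcast_to(p["W2"][:, 1] - p["W2"][:, 0], a1.shape)
    g_z1 = g_a1 * (z1 > 0)
    g_flat = g_z1 @ p["W1"].T
    g_pool = g_flat.reshape(n, nb, F)
    g_trim = np.zeros_like(trimmed)
    np.put_along_axis(g_trim, arg[:, :, None], g_pool[:, :, None], axis=2)
    g_ac = np.zeros_like(zc)
    g_ac[:, : nb * pw] = g_trim.reshape(n, nb * pw, F)
    g_zc = g_ac * (zc > 0)
    g_fwin = (g_zc @ p["Wc"].T).reshape(n, model.conv_out, model.cfg.kernel_width, 5)
    g_X = np.zeros_like(X)
    for t in range(model.cfg.kernel_width):
        g_X[:, t : t + model.conv_out] += g_fwin[:, :, t]
    return g_X * X
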