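"""Motion compensation by re-evaluating traces at drift-corrected positions.

Positive estimated motion means the tissue moved up (toward larger y); the
corrected trace of a channel is therefore read from the recorded field at the
channel's position *shifted up by the motion*, so that channels virtually
follow the tissue. Kernels map source channels (the physical electrodes) to
target positions (the shifted electrodes) and are recomputed once per
temporal bin of the motion estimate, then applied to every sample in the bin.

Kernel matrices have shape ``(n_source, n_target)`` and are applied as
``traces @ W``; each column holds the source weights of one target and sums
to 1 (snap columns are one-hot), so interpolated samples are convex
combinations of source samples.
"""

from __future__ import annotations

import numpy as np

from .core import ProbeGeometry, Recording
from .motion_estimate import Motion

__all__ = [
    "corrected_positions",
    "snap_kernel",
    "idw_kernel",
    "kriging_kernel",
    "interpolate_recording",
    "INTERPOLATE_METHODS",
]

INTERPOLATE_METHODS = ("snap", "idw", "kriging")


def corrected_positions(
    probe: ProbeGeometry, motion: Motion, t_bin: int
) -> np.ndarray:
    """Per-channel drift-corrected positions ``(x, y + m(y, t))`` at bin ``t_bin``.

    The motion is linearly interpolated across spatial window centers with
    constant extrapolation beyond the outermost windows.
    """
    t = motion.t_centers[t_bin]
    m = motion.displacement_at(probe.y, [t])[0]
    out = probe.positions.copy()
    out[:, 1] += m
    return out


def snap_kernel(src_positions: np.ndarray, tgt_positions: np.ndarray) -> np.ndarray:
    """Each target takes its nearest source channel (ties: lowest channel id)."""
    d = np.linalg.norm(
        np.asarray(tgt_positions)[:, None, :] - np.asarray(src_positions)[None, :, :],
        axis=2,
    )
    nearest = np.argmin(d, axis=1)        # first minimum = lowest channel id
    w = np.zeros((len(src_positions), len(tgt_positions)))
    w[nearest, np.arange(len(tgt_positions))] = 1.0
    return w


def idw_kernel(
    src_positions: np.ndarray,
    tgt_positions: np.ndarray,
    n_nearest: int = 3,
    coincidence_um: float = 1e-9,
) -> np.ndarray:
    """Inverse-squared-distance weights over the ``n_nearest`` source channels.

    A target closer than ``coincidence_um`` to a source receives unit weight
    on that source. Columns are normalized to sum to 1.
    """
    src = np.asarray(src_positions, dtype=np.float64)
    tgt = np.asarray(tgt_positions, dtype=np.float64)
    d = np.linalg.norm(tgt[:, None, :] - src[None, :, :], axis=2)
    n_nearest = min(n_nearest, src.shape[0])
    w = np.zeros((src.shape[0], tgt.shape[0]))
    for j in range(tgt.shape[0]):
        order = np.argsort(d[j], kind="stable")[:n_nearest]
        if d[j, order[0]] < coincidence_um:
            w[order[0], j] = 1.0
            continue
        inv = 1.0 / d[j, order] ** 2
        w[order, j] = inv / inv.sum()
    return w


def kriging_kernel(
    src_positions: np.ndarray,
    tgt_positions: np.ndarray,
    sigma_x_um: float = 20.0,
    sigma_y_um: float = 30.0,
    ridge: float = 0.01,
    eps: float = 0.001,
) -> np.ndarray:
    """Kriging weights from negatively exponentiated city-block distances.

    ``K_xx`` and ``K_yx`` use ``exp(-|dx|/sigma_x - |dy|/sigma_y)``; the raw
    kernel is ``K_yx (K_xx + ridge I)^{-1}``. Entries below ``eps`` (including
    any negative ones) are zeroed before each column is normalized to sum to
    1. A column that sparsifies to zero falls back to snapping its target to
    the nearest source, so the kernel never degenerates.
    """
    src = np.asarray(src_positions, dtype=np.float64)
    tgt = np.asarray(tgt_positions, dtype=np.float64)

    def k_mat(a, b):
        dx = np.abs(a[:, None, 0] - b[None, :, 0])
        dy = np.abs(a[:, None, 1] - b[None, :, 1])
        return np.exp(-dx / sigma_x_um - dy / sigma_y_um)

    k_xx = k_mat(src, src)
    k_yx = k_mat(tgt, src)                        # (n_tgt, n_src)
    raw = np.linalg.solve(k_xx + ridge * np.eye(len(src)), k_yx.T)
    raw[raw < eps] = 0.0
    sums = raw.sum(axis=0)
    dead = sums <= 0
    if np.any(dead):
        d = np.linalg.norm(tgt[dead][:, None, :] - src[None, :, :], axis=2)
        raw[:, dead] = 0.0
        raw[np.argmin(d, axis=1), np.flatnonzero(dead)] = 1.0
        sums = raw.sum(axis=0)
    return raw / sums[None, :]


_KERNELS = {"snap": snap_kernel, "idw": idw_kernel, "kriging": kriging_kernel}


def interpolate_recording(
    rec: Recording,
    motion: Motion,
    method: str = "kriging",
    border_mode: str = "remove_channels",
    **kernel_kwargs,
) -> Recording:
    """Apply motion compensation to a recording, one kernel per temporal bin.

    ``border_mode='remove_channels'`` drops channels within the maximum
    absolute estimated motion of the probe's y extremes, where interpolation
    has no source data; ``'keep'`` retains the full geometry.
    """
    if method not in _KERNELS:
        raise ValueError(f"unknown interpolation method '{method}' "
                         f"(options: {INTERPOLATE_METHODS})")
    if border_mode not in ("remove_channels", "keep"):
        raise ValueError(f"unknown border_mode '{border_mode}'")
    geom = rec.geometry
    y = geom.y
    if border_mode == "remove_channels":
        margin = motion.max_abs()
        keep = (y >= y.min() + margin) & (y <= y.max() - margin)
        if not np.any(keep):
            raise ValueError("border removal would drop every channel")
    else:
        keep = np.ones(len(y), dtype=bool)
    keep_idx = np.flatnonzero(keep)

    tc = motion.t_centers
    edges = np.empty(len(tc) + 1)
    edges[1:-1] = 0.5 * (tc[:-1] + tc[1:])
    edges[0] = 0.0
    edges[-1] = rec.duration
    fs = rec.sampling_rate
    n_keep = len(keep_idx)
    out = np.empty((rec.n_samples, n_keep), dtype=np.float32)
    kernel_fn = _KERNELS[method]
    for t_bin in range(len(tc)):
        a = int(round(edges[t_bin] * fs))
        b = int(round(edges[t_bin + 1] * fs)) if t_bin < len(tc) - 1 else rec.n_samples
        if b <= a:
            continue
        tgt = corrected_positions(geom, motion, t_bin)[keep_idx]
        w = kernel_fn(geom.positions, tgt, **kernel_kwargs).astype(np.float32)
        chunk = 1 << 20
        for ca in range(a, b, chunk):
            cb = min(ca + chunk, b)
            out[ca:cb] = rec.get_traces(ca, cb) @ w
    return Recording(out, fs, geom.select(keep_idx), provenance="corrected")
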