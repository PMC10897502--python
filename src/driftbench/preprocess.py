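"""Preprocessing chain applied before motion correction.

Replicates the usual Kilosort-style chain: zero-phase highpass at 150 Hz,
common median reference, and local whitening with a 150 um neighborhood
radius. Operations return new in-memory recordings with the ``preprocessed``
provenance tag; they are deterministic given the recording and the whitening
subsample seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .core import Recording

__all__ = ["highpass", "common_median_reference", "whiten_local", "preprocess_chain"]


def highpass(rec: Recording, cutoff: float = 150.0, order: int = 3,
             chunk_s: float = 10.0, margin_s: float = 0.5) -> Recording:
    """Zero-phase (forward-backward) Butterworth highpass filter.

    ``cutoff`` must lie below the Nyquist frequency. Forward-backward
    application doubles the effective order and cancels phase shifts, so spike
    times are not displaced. Long recordings are filtered in overlapping
    chunks (``margin_s`` of context on each side); the filter transient at
    150 Hz decays well within the margin, so chunked and whole-array
    application agree to numerical precision away from the recording edges.
    """
    nyq = rec.sampling_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, cutoff / nyq, btype="highpass", output="sos")
    n = rec.n_samples
    out = np.empty((n, rec.n_channels), dtype=np.float32)
    step = max(1, int(round(chunk_s * rec.sampling_rate)))
    margin = int(round(margin_s * rec.sampling_rate))
    for a in range(0, n, step):
        b = min(a + step, n)
        lo = max(0, a - margin)
        hi = min(n, b + margin)
        block = signal.sosfiltfilt(sos, rec.get_traces(lo, hi), axis=0)
        out[a:b] = block[a - lo:b - lo]
    return Recording(out, rec.sampling_rate, rec.geometry, "preprocessed")


def common_median_reference(rec: Recording) -> Recording:
    """Subtract the cross-channel median from every channel at each sample."""
    if rec.n_channels < 2:
        warnings.warn("single-channel recording: common median reference is a no-op")
        return Recording(rec.get_traces().copy(), rec.sampling_rate,
                         rec.geometry, "preprocessed")
    traces = rec.get_traces()
    out = np.empty_like(traces, dtype=np.float32)
    chunk = 1 << 20
    for a in range(0, rec.n_samples, chunk):
        b = min(a + chunk, rec.n_samples)
        block = traces[a:b]
        out[a:b] = block - np.median(block, axis=1, keepdims=True)
    return Recording(out, rec.sampling_rate, rec.geometry, "preprocessed")


def whiten_local(
    rec: Recording,
    radius: float = 150.0,
    subsample_s: float = 10.0,
    ridge_rel: float = 1e-6,
    seed: int = 0,
) -> Recording:
    """Local whitening: decorrelate each channel against its spatial neighbors.

    For every channel ``c`` the covariance of the channel group within
    ``radius`` um is estimated on a seeded random subsample (about
    ``subsample_s`` seconds), and the row of the symmetric inverse square root
    (ZCA) of that local covariance belonging to ``c`` becomes the channel's
    whitening filter. A relative ridge ``ridge_rel * mean(diag)`` keeps the
    inverse well posed for near-singular neighborhoods. With a radius smaller
    than the channel spacing the neighborhood is the channel itself and the
    operation reduces to per-channel z-scoring.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rng = np.random.default_rng([int(seed), 201])
    n_sub = min(rec.n_samples, max(1000, int(subsample_s * rec.sampling_rate)))
    idx = np.sort(rng.choice(rec.n_samples, size=n_sub, replace=False))
    sample = rec.get_traces()[idx].astype(np.float64)
    pos = rec.geometry.positions
    n_ch = rec.n_channels
    cov = (sample.T @ sample) / n_sub

    w = np.zeros((n_ch, n_ch))
    for c in range(n_ch):
        d = np.linalg.norm(pos - pos[c], axis=1)
        neigh = np.flatnonzero(d <= radius)
        local = cov[np.ix_(neigh, neigh)]
        ridge = ridge_rel * np.trace(local) / len(neigh)
        vals, vecs = np.linalg.eigh(local + ridge * np.eye(len(neigh)))
        vals = np.maximum(vals, 1e-12)
        inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
        w[c, neigh] = inv_sqrt[np.flatnonzero(neigh == c)[0]]

    traces = rec.get_traces()
    out = np.empty_like(traces, dtype=np.float32)
    chunk = 1 << 20
    wt = w.T.astype(np.float32)
    for a in range(0, rec.n_samples, chunk):
        b = min(a + chunk, rec.n_samples)
        out[a:b] = traces[a:b] @ wt
    return Recording(out, rec.sampling_rate, rec.geometry, "preprocessed")


def preprocess_chain(
    rec: Recording,
    cutoff: float = 150.0,
    cmr: bool = True,
    whiten_radius: float | None = 150.0,
    seed: int = 0,
) -> Recording:
    """highpass -> common median reference -> local whitening."""
    out = highpass(rec, cutoff)
    if cmr:
        out = common_median_reference(out)
    if whiten_radius is not None:
        out = whiten_local(out, whiten_radius, seed=seed)
    return out
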