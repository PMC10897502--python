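"""Motion inference from activity histograms.

Two algorithms estimate the displacement of the tissue relative to the probe
from the time-resolved depth profile of detected spikes:

* **iterative template** (Kilosort 2.5 style) — each 2 s temporal bin of a
  3-D (time x depth x log-amplitude) histogram is aligned to an iteratively
  updated average template by maximizing the mean elementwise product over
  integer spatial shifts; a non-iterated per-block pass adds the non-rigid
  refinement on 50 um depth windows;
* **decentralized** — normalized cross-correlations between every pair of
  temporal bins of a 2-D (time x depth) histogram (optionally limited to a
  time horizon) give pairwise displacements, which are combined into one
  displacement per bin by weighted least squares (LSMR); for non-rigid
  estimation the procedure runs per Gaussian-tapered 50 um spatial window and
  a quadratic smoothness prior couples adjacent windows.

Sign convention: positive displacement means the tissue (and the spikes'
depths) moved toward larger y. ``D[i, j]`` of the pairwise matrix estimates
``d_j - d_i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import lsmr

from .detect_localize import PeakLocations

__all__ = [
    "ActivityHistogram",
    "PairwiseDisplacement",
    "Motion",
    "make_activity_histogram",
    "estimate_motion_iterative",
    "compute_pairwise_displacement",
    "solve_displacement",
    "estimate_motion_decentralized",
    "motion_from_drift_field",
    "INFER_METHODS",
]

INFER_METHODS = ("iterative", "decentralized")


@dataclass
class ActivityHistogram:
    """Spike counts binned by time and depth (and optionally log-amplitude)."""

    counts: np.ndarray                 # (n_time_bins, n_depth_bins)
    t_edges: np.ndarray                # seconds, len n_time_bins + 1
    y_edges: np.ndarray                # um, len n_depth_bins + 1
    counts3d: np.ndarray | None = None  # (n_time, n_depth, n_amp)
    a_edges: np.ndarray | None = None
    n_clipped: int = 0

    @property
    def t_centers(self) -> np.ndarray:
        return 0.5 * (self.t_edges[:-1] + self.t_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def bin_s(self) -> float:
        return float(self.t_edges[1] - self.t_edges[0])

    @property
    def bin_um(self) -> float:
        return float(self.y_edges[1] - self.y_edges[0])


def make_activity_histogram(
    peaks: pd.DataFrame,
    locs: PeakLocations,
    duration: float,
    sampling_rate: float,
    y_range: tuple,
    bin_s: float = 2.0,
    bin_um: float = 5.0,
    with_amplitude: bool = False,
    n_amp_bins: int = 20,
) -> ActivityHistogram:
    """Bin peak depths (and optionally log10 amplitudes) over time.

    Depths outside ``y_range`` are clipped to the edge bins (their count is
    reported in ``n_clipped``); amplitude bins are 20 equal bins of
    log10(|amplitude|) between the 1st and 99th percentile.
    """
    if len(locs) != len(peaks):
        raise ValueError("need one location per peak")
    t_edges = np.arange(0.0, duration + bin_s * 0.999, bin_s)
    if t_edges[-1] < duration:
        t_edges = np.append(t_edges, duration)
    y_lo, y_hi = y_range
    y_edges = np.arange(y_lo, y_hi + bin_um * 0.999, bin_um)
    if len(peaks) == 0:
        warnings.warn("empty peak table: all-zero activity histogram")
        shape = (len(t_edges) - 1, len(y_edges) - 1)
        hist3 = np.zeros(shape + (n_amp_bins,)) if with_amplitude else None
        return ActivityHistogram(np.zeros(shape), t_edges, y_edges, hist3)

    t = peaks["frame"].to_numpy() / sampling_rate
    y = np.asarray(locs.y, dtype=np.float64)
    n_clipped = int(((y < y_lo) | (y > y_hi)).sum())
    eps = 1e-9 * max(1.0, abs(y_hi))
    y = np.clip(y, y_lo, y_hi - eps)
    t = np.clip(t, 0.0, duration - 1e-9)
    counts, _, _ = np.histogram2d(t, y, bins=[t_edges, y_edges])
    counts3d = a_edges = None
    if with_amplitude:
        amp = np.log10(np.maximum(np.abs(peaks["amplitude"].to_numpy()), 1e-12))
        lo, hi = np.percentile(amp, [1, 99])
        if hi <= lo:
            hi = lo + 1e-6
        a_edges = np.linspace(lo, hi, n_amp_bins + 1)
        amp = np.clip(amp, lo, hi - 1e-12)
        counts3d, _ = np.histogramdd(
            np.column_stack([t, y, amp]), bins=[t_edges, y_edges, a_edges]
        )
    return ActivityHistogram(counts, t_edges, y_edges, counts3d, a_edges,
                             n_clipped)


@dataclass
class Motion:
    """Displacement estimates on temporal bins x spatial windows (um)."""

    displacement: np.ndarray      # (n_time_bins, n_windows)
    t_centers: np.ndarray         # seconds
    window_centers: np.ndarray    # depth um, sorted; one window => rigid
    method: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.displacement = np.atleast_2d(np.asarray(self.displacement,
                                                     dtype=np.float64))
        self.t_centers = np.asarray(self.t_centers, dtype=np.float64)
        self.window_centers = np.atleast_1d(np.asarray(self.window_centers,
                                                       dtype=np.float64))
        if not np.all(np.diff(self.window_centers) > 0) and len(self.window_centers) > 1:
            raise ValueError("window centers must be sorted by depth")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")

    @property
    def is_rigid(self) -> bool:
        return self.displacement.shape[1] == 1

    def displacement_at(self, depths, times) -> np.ndarray:
        """Bilinear displacement lookup, constant extrapolation outside.

        Returns an array of shape ``(len(times), len(depths))`` (inputs may be
        scalars).
        """
        depths = np.atleast_1d(np.asarray(depths, dtype=np.float64))
        times = np.atleast_1d(np.asarray(times, dtype=np.float64))
        # time interpolation per window, then depth interpolation
        per_win = np.empty((len(times), self.displacement.shape[1]))
        for w in range(self.displacement.shape[1]):
            per_win[:, w] = np.interp(times, self.t_centers,
                                      self.displacement[:, w])
        if self.displacement.shape[1] == 1:
            return np.repeat(per_win, len(depths), axis=1)
        out = np.empty((len(times), len(depths)))
        for i, d in enumerate(depths):
            out[:, i] = np.array(
                [np.interp(d, self.window_centers, per_win[t])
                 for t in range(len(times))]
            )
        return out

    def max_abs(self) -> float:
        return float(np.abs(self.displacement).max())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.displacement,
                          columns=[f"win_{c:.1f}" for c in self.window_centers])
        df.insert(0, "t_center", self.t_centers)
        return df


def _shift_rows(a: np.ndarray, s: int) -> np.ndarray:
    """Shift content of the depth axis (last axis) by ``s`` bins, zero fill."""
    out = np.zeros_like(a)
    if s == 0:
        out[...] = a
    elif s > 0:
        out[..., s:] = a[..., :-s]
    else:
        out[..., :s] = a[..., -s:]
    return out


def estimate_motion_iterative(
    hist3d: ActivityHistogram,
    max_shift_bins: int = 15,
    window_um: float = 50.0,
    rigid: bool = False,
    max_iter: int = 20,
) -> Motion:
    """Iterative-template registration on the 3-D activity histogram.

    The rigid pass aligns every temporal bin to a target template (initialized
    from the central temporal bin, iteratively replaced by the mean of the
    aligned bins) over integer shifts of up to ``max_shift_bins`` spatial
    bins; iteration stops when no shift changes or after ``max_iter`` rounds.
    With ``rigid=False`` a single non-iterated per-block pass on ``window_um``
    depth blocks refines each block's displacement.
    """
    if hist3d.counts3d is None:
        raise ValueError("iterative method needs the 3-D (amplitude) histogram")
    h = hist3d.counts3d.astype(np.float64)        # (T, Y, A)
    n_t, n_y, _ = h.shape
    bin_um = hist3d.bin_um
    shifts = np.arange(-max_shift_bins, max_shift_bins + 1)
    # depth axis is axis 1; move it last for _shift_rows
    hm = np.moveaxis(h, 1, 2)                      # (T, A, Y)

    zero_bins = h.sum(axis=(1, 2)) == 0
    target = hm[n_t // 2].copy()
    best = np.zeros(n_t, dtype=np.int64)
    for _ in range(max_iter):
        scores = np.empty((len(shifts), n_t))
        for si, s in enumerate(shifts):
            shifted = _shift_rows(hm, -s)          # undo displacement s
            scores[si] = np.einsum("tay,ay->t", shifted, target) / target.size
        new_best = shifts[np.argmax(scores, axis=0)]
        new_best[zero_bins] = 0
        aligned = np.stack([_shift_rows(hm[t], -new_best[t])
                            for t in range(n_t)])
        target = aligned.mean(axis=0)
        if np.array_equal(new_best, best):
            best = new_best
            break
        best = new_best

    rigid_disp = best * bin_um
    y_centers = hist3d.y_centers
    if rigid:
        center = np.array([0.5 * (hist3d.y_edges[0] + hist3d.y_edges[-1])])
        return Motion(rigid_disp[:, None], hist3d.t_centers, center,
                      method="iterative",
                      flags={"zero_bins": int(zero_bins.sum())})

    # non-rigid refinement: one Gaussian-tapered alignment pass per depth block
    n_blocks = max(1, int(np.ceil((hist3d.y_edges[-1] - hist3d.y_edges[0])
                                  / window_um)))
    bins_per_block = max(1, int(round(window_um / bin_um)))
    disp = np.zeros((n_t, n_blocks))
    centers = np.empty(n_blocks)
    aligned = np.stack([_shift_rows(hm[t], -best[t]) for t in range(n_t)])
    for bidx in range(n_blocks):
        lo = bidx * bins_per_block
        hi = min(n_y, lo + bins_per_block)
        centers[bidx] = 0.5 * (hist3d.y_edges[lo] + hist3d.y_edges[min(hi, n_y)])
        # taper suppresses mass sliding in from neighboring depth blocks
        taper = np.exp(-0.5 * ((hist3d.y_centers - centers[bidx]) / window_um) ** 2)
        tgt_block = target * taper[None, :]
        scores = np.empty((len(shifts), n_t))
        for si, s in enumerate(shifts):
            shifted = _shift_rows(aligned, -s) * taper[None, None, :]
            scores[si] = np.einsum("tay,ay->t", shifted, tgt_block) / tgt_block.size
        block_best = shifts[np.argmax(scores, axis=0)]
        block_best[zero_bins] = 0
        disp[:, bidx] = (best + block_best) * bin_um
    return Motion(disp, hist3d.t_centers, centers, method="iterative",
                  flags={"zero_bins": int(zero_bins.sum())})


@dataclass
class PairwiseDisplacement:
    """All-pairs displacement estimates between temporal bins.

    ``D[i, j]`` estimates ``d_j - d_i`` in um (antisymmetric); ``W`` holds the
    cross-correlation confidence in [0, 1] (symmetric); entries outside the
    time horizon are zero-weighted.
    """

    D: np.ndarray
    W: np.ndarray
    t_centers: np.ndarray
    horizon_s: float | None = None


def compute_pairwise_displacement(
    hist2d: ActivityHistogram,
    max_shift_bins: int = 15,
    horizon_s: float | None = 120.0,
    counts: np.ndarray | None = None,
) -> PairwiseDisplacement:
    """Pairwise displacements by normalized cross-correlation of depth rows.

    The best integer shift is refined to sub-bin resolution by a parabolic
    fit through the correlation at the maximum and its two neighbors; the
    weight is the correlation value at the maximum, floored at 0.
    """
    rows = (hist2d.counts if counts is None else counts).astype(np.float64)
    n_t, n_y = rows.shape
    if n_t < 2:
        raise ValueError("need at least 2 temporal bins")
    max_shift_bins = min(max_shift_bins, n_y - 1)
    bin_um = hist2d.bin_um
    rc = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rc, axis=1)
    good = norms > 0
    safe = np.where(good, norms, 1.0)

    shifts = np.arange(-max_shift_bins, max_shift_bins + 1)
    corr = np.empty((len(shifts), n_t, n_t))
    for si, s in enumerate(shifts):
        if s >= 0:
            a = rc[:, : n_y - s] if s > 0 else rc
            b = rc[:, s:]
        else:
            a = rc[:, -s:]
            b = rc[:, :s]
        corr[si] = (a @ b.T) / np.outer(safe, safe)

    best = np.argmax(corr, axis=0)
    w = np.take_along_axis(corr, best[None], axis=0)[0]
    np.maximum(w, 0.0, out=w)

    # parabolic sub-bin refinement
    delta = np.zeros((n_t, n_t))
    inner = (best > 0) & (best < len(shifts) - 1)
    ii, jj = np.nonzero(inner)
    cm = corr[best[ii, jj] - 1, ii, jj]
    c0 = corr[best[ii, jj], ii, jj]
    cp = corr[best[ii, jj] + 1, ii, jj]
    denom = cm - 2 * c0 + cp
    ok = np.abs(denom) > 1e-12
    d = np.zeros(len(ii))
    d[ok] = 0.5 * (cm[ok] - cp[ok]) / denom[ok]
    delta[ii, jj] = np.clip(d, -0.5, 0.5)

    D = (shifts[best] + delta) * bin_um
    w[~good, :] = 0.0
    w[:, ~good] = 0.0
    if horizon_s is not None:
        tc = hist2d.t_centers
        mask = np.abs(tc[:, None] - tc[None, :]) > horizon_s
        w[mask] = 0.0
        D[mask] = 0.0
    # enforce the exact algebraic properties
    D = 0.5 * (D - D.T)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(D, 0.0)
    return PairwiseDisplacement(D, w, hist2d.t_centers, horizon_s)


def solve_displacement(pd_: PairwiseDisplacement) -> tuple[np.ndarray, dict]:
    """Weighted least-squares displacement from pairwise estimates.

    Minimizes ``sum_ij W_ij (d_j - d_i - D_ij)^2`` with the LSMR sparse
    solver. The gauge is fixed by ``median(d) = 0`` per connected component
    of the weight graph; multiple components are flagged.
    """
    n = pd_.D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = pd_.W[iu, ju]
    keep = w > 0
    flags = {"n_components": 1, "empty": False}
    if not np.any(keep):
        flags["empty"] = True
        return np.zeros(n), flags
    iu, ju, w = iu[keep], ju[keep], w[keep]
    rhs = pd_.D[iu, ju]
    sw = np.sqrt(w)
    m = len(iu)
    rows = np.repeat(np.arange(m), 2)
    cols = np.column_stack([iu, ju]).ravel()
    vals = np.column_stack([-sw, sw]).ravel()
    a = coo_matrix((vals, (rows, cols)), shape=(m, n)).tocsr()
    d = lsmr(a, sw * rhs, atol=1e-10, btol=1e-10)[0]

    adj = coo_matrix((w, (iu, ju)), shape=(n, n))
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    flags["n_components"] = int(n_comp)
    for c in range(n_comp):
        mask = labels == c
        d[mask] -= np.median(d[mask])
    return d, flags


def estimate_motion_decentralized(
    hist2d: ActivityHistogram,
    window_um: float = 50.0,
    horizon_s: float | None = 120.0,
    smoothness: float = 1.0,
    max_shift_bins: int = 15,
    rigid: bool = False,
    taper_sd_factor: float = 3.0,
) -> Motion:
    """Decentralized registration, rigid or per-50-um-window non-rigid.

    Non-rigid estimation builds Gaussian-tapered sub-histograms per spatial
    window (taper SD = ``taper_sd_factor * window_um``), solves each window
    independently, then jointly re-solves with a quadratic smoothness penalty
    of weight ``smoothness`` on adjacent-window differences. Windows without
    counts take the interpolation of their neighbors and are flagged.
    """
    y_lo, y_hi = hist2d.y_edges[0], hist2d.y_edges[-1]
    flags = {}
    if rigid or (y_hi - y_lo) <= window_um:
        pw = compute_pairwise_displacement(hist2d, max_shift_bins, horizon_s)
        d, f = solve_displacement(pw)
        flags.update(f)
        center = np.array([0.5 * (y_lo + y_hi)])
        return Motion(d[:, None], hist2d.t_centers, center,
                      method="decentralized", flags=flags)

    n_win = int(np.ceil((y_hi - y_lo) / window_um))
    centers = y_lo + window_um * (np.arange(n_win) + 0.5)
    centers = np.minimum(centers, y_hi)
    yc = hist2d.y_centers
    n_t = hist2d.counts.shape[0]
    d_hat = np.zeros((n_t, n_win))
    empty = np.zeros(n_win, dtype=bool)
    sd = taper_sd_factor * window_um
    for wi, c in enumerate(centers):
        taper = np.exp(-0.5 * ((yc - c) / sd) ** 2)
        sub = hist2d.counts * taper[None, :]
        if sub.sum() <= 0:
            empty[wi] = True
            continue
        pw = compute_pairwise_displacement(hist2d, max_shift_bins, horizon_s,
                                           counts=sub)
        d_hat[:, wi], f = solve_displacement(pw)
    if np.any(empty):
        flags["empty_windows"] = np.flatnonzero(empty).tolist()
        filled = np.flatnonzero(~empty)
        if len(filled):
            for wi in np.flatnonzero(empty):
                d_hat[:, wi] = np.array(
                    [np.interp(centers[wi], centers[filled], d_hat[t, filled])
                     for t in range(n_t)]
                )

    if smoothness > 0 and n_win > 1:
        lap = np.zeros((n_win, n_win))
        for wi in range(n_win - 1):
            lap[wi, wi] += 1.0
            lap[wi + 1, wi + 1] += 1.0
            lap[wi, wi + 1] -= 1.0
            lap[wi + 1, wi] -= 1.0
        a = np.eye(n_win) + smoothness * lap
        d_hat = np.linalg.solve(a, d_hat.T).T
    return Motion(d_hat, hist2d.t_centers, centers, method="decentralized",
                  flags=flags)


def motion_from_drift_field(drift, t_centers, window_centers) -> Motion:
    """Sample a ground-truth drift field onto a motion grid."""
    window_centers = np.atleast_1d(np.asarray(window_centers, dtype=np.float64))
    disp = np.column_stack([drift.at(c, t_centers) for c in window_centers])
    return Motion(disp, np.asarray(t_centers, dtype=np.float64),
                  window_centers, method="ground_truth")
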