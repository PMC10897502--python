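"""Ground-truth evaluation: motion error, waveform dispersion, spike agreement.

* Motion error — absolute difference between ground-truth and estimated
  displacement per (depth window, time bin), after aligning the medians of
  the two signals (the registration gauge is arbitrary), with per-depth,
  per-time and global means.
* Waveform dispersion — per-unit spike-waveform STD around the mean template
  on the unit's five best channels, normalized by the template RMS; the ratio
  against the matched static twin quantifies how much variability drift (or
  an imperfect correction) adds.
* Agreement — one-to-one spike matching within a time tolerance gives the
  agreement score TP / (N_i + N_j - TP), unit classification
  (well-detected / overmerged / redundant / false-positive) and ground-truth
  informed merging of oversplit sorted units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Recording, SortingGT
from .motion_estimate import Motion

__all__ = [
    "MotionError",
    "align_median_offset",
    "motion_error",
    "waveform_dispersion",
    "dispersion_ratio",
    "agreement_matrix",
    "classify_units",
    "gt_merge",
    "AgreementReport",
]


# ---------------------------------------------------------------------------
# motion error
# ---------------------------------------------------------------------------

@dataclass
class MotionError:
    """Absolute motion-estimation error (um) per depth window and time bin."""

    error: np.ndarray            # (n_windows, n_time_bins), >= 0
    t_centers: np.ndarray
    window_centers: np.ndarray

    @property
    def mean_over_time(self) -> np.ndarray:
        """Error profile along depth."""
        return self.error.mean(axis=1)

    @property
    def mean_over_depth(self) -> np.ndarray:
        """Error evolution over time."""
        return self.error.mean(axis=0)

    @property
    def global_mean(self) -> float:
        return float(self.error.mean())


def _resample_to(est: Motion, gt: Motion) -> np.ndarray:
    """Estimated displacement sampled on the GT (time, window) grid."""
    return est.displacement_at(gt.window_centers, gt.t_centers)


def align_median_offset(gt: Motion, est: Motion) -> Motion:
    """Shift the estimate so its global median matches the ground truth.

    The estimate is first resampled onto the GT bin grid by linear
    interpolation, then shifted by ``median(gt - est)`` computed over all
    bins; registration only determines displacement up to a constant.
    """
    disp = _resample_to(est, gt)
    offset = np.median(gt.displacement - disp)
    return Motion(disp + offset, gt.t_centers, gt.window_centers,
                  method=est.method, flags=dict(est.flags))


def motion_error(gt: Motion, est: Motion, align: bool = True) -> MotionError:
    """|gt - est| on the GT grid (median-aligned unless ``align=False``)."""
    est_a = align_median_offset(gt, est) if align else Motion(
        _resample_to(est, gt), gt.t_centers, gt.window_centers)
    err = np.abs(gt.displacement - est_a.displacement)
    return MotionError(err.T, gt.t_centers, gt.window_centers)


# ---------------------------------------------------------------------------
# waveform dispersion
# ---------------------------------------------------------------------------

def waveform_dispersion(
    rec: Recording,
    gt: SortingGT,
    n_best_channels: int = 5,
    waveform_ms: float = 2.0,
    min_spikes: int = 2,
    channels_per_unit: dict | None = None,
    max_spikes_per_unit: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit waveform dispersion normalized by template RMS.

    For each unit, ground-truth-timed waveforms are extracted on its
    ``n_best_channels`` best channels (most negative template amplitude,
    computed from this recording unless ``channels_per_unit`` overrides them,
    e.g. with the static twin's choice). The dispersion ``sigma`` is the mean
    over samples and channels of the across-spike STD, divided by the RMS of
    the mean template. Units with fewer than ``min_spikes`` usable spikes are
    dropped and reported with NaN.
    """
    fs = rec.sampling_rate
    m = int(round(waveform_ms / 1000.0 * fs))
    half = m // 2
    traces = rec.get_traces()
    rng = np.random.default_rng([int(seed), 401])
    rows = []
    chan_used = {}
    for u in gt.unit_ids:
        frames = gt.spikes[int(u)]
        frames = frames[(frames - half >= 0) & (frames - half + m <= rec.n_samples)]
        if max_spikes_per_unit is not None and len(frames) > max_spikes_per_unit:
            frames = np.sort(rng.choice(frames, size=max_spikes_per_unit,
                                        replace=False))
        if len(frames) < min_spikes:
            rows.append((int(u), np.nan, np.nan, len(frames)))
            continue
        idx = frames[:, None] + (np.arange(m) - half)[None, :]
        wf = traces[idx]                              # (n_spikes, m, n_ch)
        template = wf.mean(axis=0)                    # (m, n_ch)
        if channels_per_unit is not None and int(u) in channels_per_unit:
            best = np.asarray(channels_per_unit[int(u)])
        else:
            best = np.argsort(template.min(axis=0), kind="stable")[:n_best_channels]
        chan_used[int(u)] = best
        wf_b = wf[:, :, best]
        tmpl_b = template[:, best]
        sigma = float(wf_b.std(axis=0).mean())
        rms = float(np.sqrt(np.mean(tmpl_b ** 2)))
        rows.append((int(u), sigma / max(rms, 1e-12), rms, len(frames)))
    df = pd.DataFrame(rows, columns=["unit_id", "sigma", "template_rms",
                                     "n_spikes"])
    df.attrs["channels_per_unit"] = chan_used
    return df


def dispersion_ratio(
    rec_test: Recording,
    rec_static: Recording,
    gt: SortingGT,
    n_best_channels: int = 5,
    max_spikes_per_unit: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit STD ratio of a test recording against its static twin.

    Best channels are chosen on the static twin and reused for the test
    recording so both conditions measure the same channels. When the test
    recording has had border channels removed, units whose static best
    channels are absent from the test geometry are excluded and reported
    with NaN ratios.
    """
    static = waveform_dispersion(rec_static, gt, n_best_channels,
                                 max_spikes_per_unit=max_spikes_per_unit,
                                 seed=seed)
    chans = static.attrs["channels_per_unit"]
    # map static channel ids into the test recording's channel indexing
    test_ids = rec_test.geometry.channel_ids
    static_ids = rec_static.geometry.channel_ids
    id_to_test = {int(cid): i for i, cid in enumerate(test_ids)}
    mapped = {}
    for u, best in chans.items():
        ids = static_ids[best]
        if all(int(c) in id_to_test for c in ids):
            mapped[u] = np.array([id_to_test[int(c)] for c in ids])
    test = waveform_dispersion(rec_test, gt, n_best_channels,
                               channels_per_unit=mapped,
                               max_spikes_per_unit=max_spikes_per_unit,
                               seed=seed)
    # array-valued .attrs confuse DataFrame.merge; strip them first
    static.attrs = {}
    test.attrs = {}
    df = static.merge(test, on="unit_id", suffixes=("_static", "_test"))
    df["ratio"] = np.where(
        df["unit_id"].isin(list(mapped)),
        df["sigma_test"] / df["sigma_static"],
        np.nan,
    )
    return df


# ---------------------------------------------------------------------------
# spike-train agreement
# ---------------------------------------------------------------------------

def _count_matches(a: np.ndarray, b: np.ndarray, delta: int) -> int:
    """One-to-one matches between two sorted spike-frame arrays within delta."""
    i = j = tp = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        d = a[i] - b[j]
        if abs(d) <= delta:
            tp += 1
            i += 1
            j += 1
        elif d > delta:
            j += 1
        else:
            i += 1
    return tp


@dataclass
class AgreementReport:
    """Agreement matrix between a GT and a sorted spiking, plus best matches."""

    matrix: pd.DataFrame               # index: gt unit ids, columns: sorted ids
    best_match: dict = field(default_factory=dict)   # gt id -> sorted id or None
    accuracy: dict = field(default_factory=dict)     # gt id -> best accuracy
    delta_frames: int = 0


def agreement_matrix(
    gt: SortingGT,
    sorted_: SortingGT,
    delta_ms: float = 0.4,
    sampling_rate: float = 32000.0,
) -> AgreementReport:
    """Agreement TP / (N_i + N_j - TP) for every GT x sorted unit pair.

    Spikes are matched one-to-one within ``delta_ms``. Each GT unit is then
    assigned its best sorted unit greedily by decreasing accuracy (ties go to
    the lower unit id), each sorted unit being assigned at most once.
    """
    if gt.n_units == 0 or sorted_.n_units == 0:
        raise ValueError("both sortings must be non-empty")
    delta = int(round(delta_ms / 1000.0 * sampling_rate))
    mat = np.zeros((gt.n_units, sorted_.n_units))
    for gi, gu in enumerate(gt.unit_ids):
        a = gt.spikes[int(gu)]
        for sj, su in enumerate(sorted_.unit_ids):
            b = sorted_.spikes[int(su)]
            tp = _count_matches(a, b, delta)
            denom = len(a) + len(b) - tp
            mat[gi, sj] = tp / denom if denom > 0 else 0.0
    df = pd.DataFrame(mat, index=gt.unit_ids.tolist(),
                      columns=sorted_.unit_ids.tolist())

    pairs = [(mat[gi, sj], int(gt.unit_ids[gi]), int(sorted_.unit_ids[sj]))
             for gi in range(gt.n_units) for sj in range(sorted_.n_units)]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    best, used = {}, set()
    for score, gu, su in pairs:
        if score <= 0:
            break
        if gu in best or su in used:
            continue
        best[gu] = su
        used.add(su)
    accuracy = {int(gu): (float(df.loc[gu, best[gu]]) if gu in best else 0.0)
                for gu in gt.unit_ids}
    for gu in gt.unit_ids:
        best.setdefault(int(gu), None)
    return AgreementReport(df, best, accuracy, delta)


def classify_units(
    report: AgreementReport,
    well_threshold: float = 0.8,
    low_threshold: float = 0.2,
) -> pd.DataFrame:
    """Classify each sorted unit by its agreements with ground truth.

    Labels (exhaustive, applied in this order of precedence):
    ``well_detected`` — the unit is some GT unit's best match with accuracy at
    or above ``well_threshold`` (the bound is inclusive); ``overmerged`` —
    agreement above ``low_threshold`` with more than one GT unit;
    ``redundant`` — agreement above ``low_threshold`` with a GT unit without
    being its best match; ``false_positive`` — all agreements at or below
    ``low_threshold``. ``bad`` aggregates the last three.
    """
    mat = report.matrix
    inv_best = {su: gu for gu, su in report.best_match.items() if su is not None}
    rows = []
    for su in mat.columns:
        col = mat[su]
        supra = col.index[col > low_threshold].tolist()
        own_gt = inv_best.get(su)
        if own_gt is not None and report.accuracy[own_gt] >= well_threshold:
            label = "well_detected"
        elif len(supra) > 1:
            label = "overmerged"
        elif any(g != own_gt for g in supra):
            label = "redundant"
        else:
            # no supra-threshold agreement, or only a sub-0.8 best match
            label = "false_positive"
        rows.append((su, label, float(col.max())))
    df = pd.DataFrame(rows, columns=["sorted_unit", "label", "max_agreement"])
    counts = df["label"].value_counts().to_dict()
    counts["bad"] = sum(counts.get(lbl, 0)
                        for lbl in ("overmerged", "redundant", "false_positive"))
    df.attrs["counts"] = counts
    return df


def gt_merge(
    sorted_: SortingGT,
    report: AgreementReport,
    threshold: float = 0.2,
    delta_ms: float = 0.4,
    sampling_rate: float = 32000.0,
) -> SortingGT:
    """Merge oversplit sorted units using ground-truth agreements.

    Each sorted unit is assigned to the GT unit it agrees best with; for each
    GT unit, all assigned sorted units with agreement at or above
    ``threshold`` are merged into one unit (duplicate spikes within
    ``delta_ms`` collapsed). The merged unit keeps the id of the member that
    is the GT unit's best match (or the lowest member id); unmerged sorted
    units pass through unchanged.
    """
    mat = report.matrix
    delta = int(round(delta_ms / 1000.0 * sampling_rate))
    assigned_gt = {}
    for su in mat.columns:
        col = mat[su]
        if float(col.max()) >= threshold:
            assigned_gt[su] = col.idxmax()
    groups = {}
    for su, gu in assigned_gt.items():
        groups.setdefault(gu, []).append(su)

    new_spikes, new_ids = {}, []
    merged_members = set()
    for gu, members in groups.items():
        best = report.best_match.get(int(gu))
        keep_id = int(best) if best in members else int(min(members))
        frames = np.sort(np.concatenate([sorted_.spikes[int(su)]
                                         for su in members]))
        if len(frames) > 1:
            keep = np.ones(len(frames), dtype=bool)
            last = frames[0]
            for i in range(1, len(frames)):
                if frames[i] - last <= delta:
                    keep[i] = False
                else:
                    last = frames[i]
            frames = frames[keep]
        new_ids.append(keep_id)
        new_spikes[keep_id] = frames
        merged_members.update(int(su) for su in members)
    for su in sorted_.unit_ids:
        if int(su) not in merged_members:
            new_ids.append(int(su))
            new_spikes[int(su)] = sorted_.spikes[int(su)]
    order = np.sort(np.array(new_ids, dtype=np.int64))
    return SortingGT(order, {int(u): new_spikes[int(u)] for u in order})
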