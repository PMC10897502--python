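"""Benchmark orchestration: scenario -> detection -> localization -> inference
-> (optional) interpolation -> evaluation, producing a tidy results table.

The desk-scale preset (64 channels, 64 units, 300 s) keeps the full
localization x inference grid tractable on a single CPU while leaving at
least ~20 peaks per 2 s histogram row; the paper-scale preset (128 channels,
256 units, 600 s) matches the source benchmark conditions.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect_localize import (LOCALIZE_METHODS, detect_peaks, extract_waveforms,
                              localize_com, localize_grid, localize_mono,
                              make_prototype, select_peaks)
from .evaluate import dispersion_ratio, motion_error
from .motion_estimate import (INFER_METHODS, estimate_motion_decentralized,
                              estimate_motion_iterative,
                              make_activity_histogram, motion_from_drift_field)
from .motion_interpolate import INTERPOLATE_METHODS, interpolate_recording
from .simulate import (DEPTH_MODES, DRIFT_KINDS, RATE_PROFILES,
                       ScenarioDescriptor, simulate_scenario)

__all__ = ["BenchmarkConfig", "run_benchmark", "registry",
           "estimate_motion_pipeline"]

_REGISTRY = {
    "localize": list(LOCALIZE_METHODS),
    "infer": list(INFER_METHODS),
    "interpolate": list(INTERPOLATE_METHODS),
    "drift": list(DRIFT_KINDS),
    "depth": list(DEPTH_MODES),
    "rate": list(RATE_PROFILES),
}


def registry(kind: str) -> list[str]:
    """Closed option set for one pipeline stage (supports plugin extension)."""
    if kind not in _REGISTRY:
        raise ValueError(f"unknown registry kind '{kind}' "
                         f"(options: {sorted(_REGISTRY)})")
    return list(_REGISTRY[kind])


def register(kind: str, name: str) -> None:
    if kind not in _REGISTRY:
        raise ValueError(f"unknown registry kind '{kind}'")
    if name not in _REGISTRY[kind]:
        _REGISTRY[kind].append(name)


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run."""

    scenarios: list = field(default_factory=lambda: ["zigzag_rigid/uniform/homogeneous"])
    localize_methods: list = field(default_factory=lambda: ["monopolar"])
    infer_methods: list = field(default_factory=lambda: ["decentralized"])
    interpolate_methods: list = field(default_factory=list)
    preset: str = "desk"
    duration: float | None = None
    seeds: list = field(default_factory=lambda: [0])
    out_dir: str | None = None
    max_peaks_localize: int = 30000
    rigid: bool = False

    def __post_init__(self):
        for m in self.localize_methods:
            if m not in _REGISTRY["localize"]:
                raise ValueError(f"unknown localization method '{m}'")
        for m in self.infer_methods:
            if m not in _REGISTRY["infer"]:
                raise ValueError(f"unknown inference method '{m}'")
        for m in self.interpolate_methods:
            if m not in _REGISTRY["interpolate"]:
                raise ValueError(f"unknown interpolation method '{m}'")

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def _parse_scenario(s, seed: int) -> ScenarioDescriptor:
    if isinstance(s, ScenarioDescriptor):
        return ScenarioDescriptor(s.drift, s.depth, s.rate, seed)
    drift, depth, rate = s.split("/")
    return ScenarioDescriptor(drift, depth, rate, seed)


def estimate_motion_pipeline(
    rec,
    localize_method: str = "monopolar",
    infer_method: str = "decentralized",
    rigid: bool = False,
    max_peaks: int | None = 30000,
    bin_s: float = 2.0,
    bin_um: float = 5.0,
    window_um: float = 50.0,
    seed: int = 0,
    _cache: dict | None = None,
):
    """Detect, localize and infer motion from a recording.

    ``_cache`` (optional dict) lets several method combinations on the same
    recording share the detection and waveform-extraction work.
    """
    cache = _cache if _cache is not None else {}
    if "peaks" not in cache:
        peaks = detect_peaks(rec, seed=seed)
        if max_peaks is not None:
            peaks = select_peaks(peaks, max_peaks, seed=seed)
        cache["peaks"] = peaks
        cache["wfs"] = extract_waveforms(rec, peaks)
    wfs = cache["wfs"]
    if ("loc", localize_method) not in cache:
        if localize_method == "com":
            loc = localize_com(wfs)
        elif localize_method == "grid":
            proto = make_prototype(wfs, seed=seed)
            loc = localize_grid(wfs, proto)
        elif localize_method == "monopolar":
            loc = localize_mono(wfs)
        else:
            raise ValueError(f"unknown localization method '{localize_method}'")
        cache[("loc", localize_method)] = loc
    loc = cache[("loc", localize_method)]

    y_range = (float(rec.geometry.y.min()), float(rec.geometry.y.max()))
    hist = make_activity_histogram(
        wfs.peaks, loc, rec.duration, rec.sampling_rate, y_range,
        bin_s=bin_s, bin_um=bin_um,
        with_amplitude=(infer_method == "iterative"),
    )
    if infer_method == "iterative":
        motion = estimate_motion_iterative(hist, window_um=window_um,
                                           rigid=rigid)
    elif infer_method == "decentralized":
        motion = estimate_motion_decentralized(hist, window_um=window_um,
                                               rigid=rigid)
    else:
        raise ValueError(f"unknown inference method '{infer_method}'")
    return motion


def interpolation_benchmark(
    scenario,
    duration: float = 240.0,
    preset: str | dict = "desk",
    methods=("kriging",),
    preprocess: bool = False,
    max_spikes_per_unit: int = 300,
    n_gt_windows: int = 9,
    workdir=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Waveform-dispersion ratios of corrected/drifting twins vs static.

    Renders a drifting recording and its static twin, optionally applies the
    preprocessing chain (highpass, common median reference, local whitening)
    to both, interpolates the drifting recording with the *ground-truth*
    motion for each method, and returns per-unit STD ratios against the
    static twin (best channels chosen on the static condition). The ``ratio``
    column carries one row per (method, unit), with method ``drifting`` for
    the uncorrected twin, plus the unit's maximum absolute GT displacement.

    Recordings are staged through ``workdir`` (a temporary directory by
    default) so that at most two trace arrays are in memory at a time.
    """
    import gc
    import tempfile

    from .core import read_recording, write_recording
    from .evaluate import waveform_dispersion
    from .motion_estimate import motion_from_drift_field
    from .motion_interpolate import interpolate_recording
    from .preprocess import preprocess_chain
    from .simulate import (build_probe, build_templates, generate_drift_signal,
                           generate_spike_trains, place_units,
                           render_recording)
    from .simulate import DESK_PRESET, PAPER_PRESET

    desc = _parse_scenario(scenario, seed)
    p = dict(DESK_PRESET if preset == "desk" else
             PAPER_PRESET if preset == "paper" else preset)
    p["duration"] = duration
    probe = build_probe(p["n_channels"], p["n_columns"], 18.0, 22.0,
                        staggered=True, electrode_size=12.0)
    positions, k = place_units(p["n_units"], probe, desc.depth, seed=seed)
    gt = generate_spike_trains(p["n_units"], duration, desc.rate, seed=seed)
    gt.positions, gt.k = positions, k
    bank = build_templates(gt, probe, seed=seed)
    drift = generate_drift_signal(desc.drift, duration, probe.y_extent,
                                  seed=seed)

    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="driftbench_interp_")
        workdir = tmp.name
    workdir = Path(workdir)
    try:
        drifting = render_recording(bank, gt, probe, drift=drift,
                                    duration=duration, seed=seed)
        write_recording(drifting, workdir / "drifting")
        del drifting
        gc.collect()

        static = render_recording(bank, gt, probe, drift=None,
                                  duration=duration, seed=seed)
        if preprocess:
            static = preprocess_chain(static, seed=seed)
        static_df = waveform_dispersion(static, gt,
                                        max_spikes_per_unit=max_spikes_per_unit,
                                        seed=seed)
        chans = static_df.attrs["channels_per_unit"]
        static_ids = static.geometry.channel_ids
        del static
        gc.collect()

        drifting = read_recording(workdir / "drifting")
        if preprocess:
            drifting = preprocess_chain(drifting, seed=seed)
        else:
            drifting = _materialize(drifting)
        tc = np.arange(1.0, duration, 2.0)
        wc = np.linspace(probe.y.min(), probe.y.max(), n_gt_windows)
        gt_motion = motion_from_drift_field(drift, tc, wc)

        s = static_df.set_index("unit_id")["sigma"]
        disp_max = {int(u): float(np.abs(drift.at(positions[i, 1],
                                                  drift.times)).max())
                    for i, u in enumerate(gt.unit_ids)}

        def ratios(rec, label):
            ids = {int(c): j for j, c in enumerate(rec.geometry.channel_ids)}
            mapped = {
                u: np.array([ids[int(c)] for c in static_ids[b]])
                for u, b in chans.items()
                if all(int(c) in ids for c in static_ids[b])
            }
            df = waveform_dispersion(rec, gt, channels_per_unit=mapped,
                                     max_spikes_per_unit=max_spikes_per_unit,
                                     seed=seed)
            r = (df.set_index("unit_id")["sigma"] / s).dropna()
            r = r[[u for u in r.index if u in mapped]]
            return pd.DataFrame({
                "method": label, "unit_id": r.index,
                "ratio": r.to_numpy(),
                "gt_disp_um": [disp_max[int(u)] for u in r.index],
            })

        out = [ratios(drifting, "drifting")]
        for meth in methods:
            corrected = interpolate_recording(drifting, gt_motion, method=meth)
            out.append(ratios(corrected, meth))
            del corrected
            gc.collect()
        return pd.concat(out, ignore_index=True)
    finally:
        if tmp is not None:
            tmp.cleanup()


def _materialize(rec):
    """Materialize a (possibly memmap-backed) recording in RAM."""
    from .core import Recording

    return Recording(np.array(rec.get_traces()), rec.sampling_rate,
                     rec.geometry, rec.provenance)


def run_benchmark(cfg: BenchmarkConfig) -> dict:
    """Run the scenario x method grid and collect error / dispersion tables.

    Returns ``{"results": DataFrame, "manifest": dict}``; when
    ``cfg.out_dir`` is set, also writes ``results.csv`` and
    ``manifest.json``. A failing cell is recorded in the manifest and the run
    continues.
    """
    rows = []
    manifest = {
        "version": __version__,
        "preset": cfg.preset,
        "duration": cfg.duration,
        "seeds": list(cfg.seeds),
        "scenarios": [str(s) for s in cfg.scenarios],
        "localize_methods": list(cfg.localize_methods),
        "infer_methods": list(cfg.infer_methods),
        "interpolate_methods": list(cfg.interpolate_methods),
        "rigid": cfg.rigid,
        "max_peaks_localize": cfg.max_peaks_localize,
        "failures": [],
        "timing_s": {},
    }
    for seed in cfg.seeds:
        for scen in cfg.scenarios:
            desc = _parse_scenario(scen, seed)
            t0 = time.perf_counter()
            pair = simulate_scenario(
                desc, preset=cfg.preset, duration=cfg.duration,
                make_static=bool(cfg.interpolate_methods),
            )
            manifest["timing_s"][f"simulate/{desc.name}/{seed}"] = round(
                time.perf_counter() - t0, 2)
            cache: dict = {}
            for lm in cfg.localize_methods:
                for im in cfg.infer_methods:
                    cell = f"{desc.name}/{seed}/{lm}+{im}"
                    t0 = time.perf_counter()
                    try:
                        est = estimate_motion_pipeline(
                            pair.drifting, lm, im, rigid=cfg.rigid,
                            max_peaks=cfg.max_peaks_localize, seed=seed,
                            _cache=cache,
                        )
                        gt_motion = motion_from_drift_field(
                            pair.drift, est.t_centers, est.window_centers)
                        err = motion_error(gt_motion, est)
                        rows.append(dict(
                            kind="motion_error", scenario=desc.name, seed=seed,
                            localize=lm, infer=im, interpolate="",
                            value=err.global_mean, units="um",
                        ))
                    except Exception as exc:  # noqa: BLE001 - cell isolation
                        manifest["failures"].append(
                            {"cell": cell, "error": repr(exc),
                             "trace": traceback.format_exc(limit=3)})
                    manifest["timing_s"][cell] = round(
                        time.perf_counter() - t0, 2)
            for meth in cfg.interpolate_methods:
                cell = f"{desc.name}/{seed}/gt+{meth}"
                t0 = time.perf_counter()
                try:
                    tc = np.arange(1.0, pair.drifting.duration, 2.0)
                    wc = np.linspace(pair.probe.y.min(), pair.probe.y.max(), 5)
                    gt_motion = motion_from_drift_field(pair.drift, tc, wc)
                    corrected = interpolate_recording(
                        pair.drifting, gt_motion, method=meth)
                    ratios = dispersion_ratio(
                        corrected, pair.static, pair.gt,
                        max_spikes_per_unit=200, seed=seed)
                    rows.append(dict(
                        kind="dispersion_ratio", scenario=desc.name, seed=seed,
                        localize="", infer="", interpolate=meth,
                        value=float(np.nanmean(ratios["ratio"])), units="",
                    ))
                except Exception as exc:  # noqa: BLE001
                    manifest["failures"].append(
                        {"cell": cell, "error": repr(exc),
                         "trace": traceback.format_exc(limit=3)})
                manifest["timing_s"][cell] = round(time.perf_counter() - t0, 2)
    results = pd.DataFrame(rows)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"results": results, "manifest": manifest}
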