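"""Core containers: probe geometry, recording, ground-truth sorting, and their on-disk formats.

Conventions used throughout the package:

* positions are 2-D ``(x, y)`` in micrometers; ``y`` is the depth axis along the
  probe shank, increasing from the probe bottom (``y = 0``) upward, and is the
  axis along which drift acts;
* traces are in microvolts, stored as 32-bit floats, time-major
  ``(n_samples, n_channels)``;
* sample indexing is 0-based and ``t = frame / sampling_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ProbeGeometry",
    "Recording",
    "SortingGT",
    "build_probe",
    "read_recording",
    "write_recording",
    "read_sorting_csv",
    "write_sorting_csv",
    "GeometryError",
    "FormatError",
]


class GeometryError(ValueError):
    """Raised for inconsistent probe-geometry requests."""


class FormatError(ValueError):
    """Raised when an on-disk recording does not match its metadata."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Channel identities and planar positions of a high-density probe.

    Parameters
    ----------
    channel_ids : ndarray of int
        One id per channel.
    positions : ndarray, shape (n_channels, 2)
        Per-channel ``(x, y)`` position in micrometers.
    electrode_size : float, optional
        Side length of the (square) electrode in micrometers; informational.
    """

    channel_ids: np.ndarray
    positions: np.ndarray
    electrode_size: float | None = None

    def __post_init__(self):
        ids = np.asarray(self.channel_ids, dtype=np.int64)
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise GeometryError("positions must have shape (n_channels, 2)")
        if len(ids) != len(pos):
            raise GeometryError("channel_ids and positions length mismatch")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise GeometryError("channel positions must be unique")
        object.__setattr__(self, "channel_ids", ids)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        """Depth coordinate (drift axis)."""
        return self.positions[:, 1]

    @property
    def y_extent(self) -> float:
        return float(self.y.max() - self.y.min())

    def select(self, mask_or_indices) -> "ProbeGeometry":
        """Sub-probe restricted to a channel subset (boolean mask or indices)."""
        return ProbeGeometry(
            self.channel_ids[mask_or_indices],
            self.positions[mask_or_indices],
            self.electrode_size,
        )

    def to_dict(self) -> dict:
        d = {
            "ids": self.channel_ids.tolist(),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
        }
        if self.electrode_size is not None:
            d["electrode_size"] = self.electrode_size
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeGeometry":
        pos = np.column_stack([d["x"], d["y"]])
        return cls(np.asarray(d["ids"]), pos, d.get("electrode_size"))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "ProbeGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_probe(
    n_channels: int,
    n_columns: int,
    x_pitch: float,
    y_pitch: float,
    staggered: bool = True,
    electrode_size: float | None = None,
) -> ProbeGeometry:
    """Build a planar multi-column probe layout.

    Channels are laid out row-major: channel ``c`` sits in row ``c // n_columns``
    and column ``c % n_columns``. Columns are spaced ``x_pitch`` apart and rows
    ``y_pitch`` apart; when ``staggered``, every odd row is offset by
    ``x_pitch / 2``, giving the hexagonal staggering of Neuropixels 1.0-style
    probes. ``y`` spans ``[0, (n_channels / n_columns - 1) * y_pitch]``.
    """
    if n_channels % n_columns != 0:
        raise GeometryError(
            f"n_channels={n_channels} not divisible by n_columns={n_columns}"
        )
    c = np.arange(n_channels)
    row = c // n_columns
    col = c % n_columns
    x = col * float(x_pitch)
    if staggered:
        x = x + (row % 2) * (x_pitch / 2.0)
    y = row * float(y_pitch)
    return ProbeGeometry(c, np.column_stack([x, y]), electrode_size)


class Recording:
    """A channels-by-time extracellular trace matrix with geometry.

    Traces are held as a float32 array of shape ``(n_samples, n_channels)`` in
    microvolts (possibly a memory map when read from disk). ``get_traces``
    guarantees that chunked reads of adjacent ranges concatenate to the same
    values as one contiguous read.
    """

    def __init__(
        self,
        traces: np.ndarray,
        sampling_rate: float,
        geometry: ProbeGeometry,
        provenance: str = "raw",
    ):
        traces = np.asarray(traces)
        if traces.ndim != 2:
            raise ValueError("traces must be 2-D (n_samples, n_channels)")
        if sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if traces.shape[1] != geometry.n_channels:
            raise ValueError("trace channel count does not match geometry")
        self._traces = traces
        self.sampling_rate = float(sampling_rate)
        self.geometry = geometry
        self.provenance = provenance

    @property
    def n_samples(self) -> int:
        return self._traces.shape[0]

    @property
    def n_channels(self) -> int:
        return self._traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def get_traces(
        self,
        start_frame: int | None = None,
        end_frame: int | None = None,
        channel_indices=None,
    ) -> np.ndarray:
        """Read a ``(samples, channels)`` block in microvolts."""
        sl = slice(start_frame, end_frame)
        if channel_indices is None:
            return np.asarray(self._traces[sl])
        return np.asarray(self._traces[sl][:, channel_indices])

    def iter_chunks(self, chunk_s: float = 1.0):
        """Yield ``(start_frame, end_frame)`` pairs tiling the recording."""
        step = max(1, int(round(chunk_s * self.sampling_rate)))
        for start in range(0, self.n_samples, step):
            yield start, min(start + step, self.n_samples)

    def select_channels(self, mask_or_indices) -> "Recording":
        return Recording(
            self._traces[:, mask_or_indices],
            self.sampling_rate,
            self.geometry.select(mask_or_indices),
            self.provenance,
        )


@dataclass
class SortingGT:
    """Ground-truth spiking: per-unit spike frames, home positions, strengths.

    ``positions`` are the units' home ``(x, y, z)`` in micrometers, ``z > 0``
    being the off-plane distance to the probe, and ``k`` the monopole source
    strength in microvolt-micrometers (peak-to-peak at distance ``d`` is
    ``k / d``).
    """

    unit_ids: np.ndarray
    spikes: dict  # unit_id -> strictly-increasing int64 frames
    positions: np.ndarray | None = None  # (n_units, 3)
    k: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        for u in self.unit_ids:
            f = np.asarray(self.spikes[int(u)], dtype=np.int64)
            if len(f) > 1 and not np.all(np.diff(f) > 0):
                raise ValueError(f"spike frames of unit {u} not strictly increasing")
            self.spikes[int(u)] = f

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def n_spikes(self, unit_id: int) -> int:
        return len(self.spikes[int(unit_id)])

    def total_spikes(self) -> int:
        return sum(len(f) for f in self.spikes.values())


# ---------------------------------------------------------------------------
# on-disk format: raw float32 little-endian time-major binary + JSON sidecar
# ---------------------------------------------------------------------------

_TRACES_FILE = "traces.raw"
_META_FILE = "meta.json"


def write_recording(rec: Recording, out_dir) -> dict:
    """Write ``traces.raw`` (float32 LE, time-major) + ``meta.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traces = np.ascontiguousarray(rec.get_traces(), dtype="<f4")
    traces.tofile(out_dir / _TRACES_FILE)
    meta = {
        "sampling_rate": rec.sampling_rate,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "provenance": rec.provenance,
        "probe": rec.geometry.to_dict(),
    }
    (out_dir / _META_FILE).write_text(json.dumps(meta))
    return meta


def read_recording(path, mmap: bool = True) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``path`` may be the directory or the ``meta.json`` file itself.
    """
    path = Path(path)
    meta_path = path / _META_FILE if path.is_dir() else path
    if not meta_path.exists():
        raise FormatError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("sampling_rate", "n_channels", "n_samples", "dtype", "probe"):
        if key not in meta:
            raise FormatError(f"metadata missing key '{key}'")
    trace_path = meta_path.parent / _TRACES_FILE
    n_channels = int(meta["n_channels"])
    n_samples = int(meta["n_samples"])
    itemsize = np.dtype(meta["dtype"]).itemsize
    expected = n_channels * n_samples * itemsize
    actual = trace_path.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{trace_path}: size {actual} B does not match metadata "
            f"({n_samples} x {n_channels} x {itemsize} B = {expected} B)"
        )
    if mmap:
        traces = np.memmap(trace_path, dtype="<f4", mode="r",
                           shape=(n_samples, n_channels))
    else:
        traces = np.fromfile(trace_path, dtype="<f4").reshape(n_samples, n_channels)
    geom = ProbeGeometry.from_dict(meta["probe"])
    return Recording(traces, meta["sampling_rate"], geom,
                     meta.get("provenance", "raw"))


def write_sorting_csv(sorting: SortingGT, path) -> None:
    """Spikes as ``unit_id,frame`` CSV rows sorted by (unit, frame)."""
    import pandas as pd

    rows = [
        (int(u), int(f))
        for u in sorting.unit_ids
        for f in sorting.spikes[int(u)]
    ]
    pd.DataFrame(rows, columns=["unit_id", "frame"]).to_csv(path, index=False)


def read_sorting_csv(path) -> SortingGT:
    import pandas as pd

    df = pd.read_csv(path)
    unit_ids = np.sort(df["unit_id"].unique())
    spikes = {
        int(u): np.sort(df.loc[df["unit_id"] == u, "frame"].to_numpy(np.int64))
        for u in unit_ids
    }
    return SortingGT(unit_ids, spikes)
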