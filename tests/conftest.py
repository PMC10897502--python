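import numpy as np
import pytest

from driftbench.core import ProbeGeometry, Recording, SortingGT, build_probe


@pytest.fixture
def small_probe():
    """16-channel, 2-column staggered probe (18/22 um pitch)."""
    return build_probe(16, 2, 18.0, 22.0, staggered=True)


@pytest.fixture
def column_probe():
    """8-channel single-column probe at 22 um pitch."""
    return build_probe(8, 1, 18.0, 22.0, staggered=False)


@pytest.fixture
def noise_recording(small_probe):
    """1 s of pure 5 uV Gaussian noise at 32 kHz."""
    rng = np.random.default_rng(1234)
    traces = 5.0 * rng.standard_normal((32000, small_probe.n_channels),
                                       dtype=np.float32)
    return Recording(traces, 32000.0, small_probe)


def make_recording(traces, probe=None, fs=32000.0):
    traces = np.asarray(traces, dtype=np.float32)
    if probe is None:
        n_ch = traces.shape[1]
        probe = build_probe(n_ch, 1, 18.0, 22.0, staggered=False)
    return Recording(traces, fs, probe)


def monopole_ptp(channel_positions, x, y, z, k):
    """Forward model: peak-to-peak amplitude of a monopole source per channel."""
    p = np.asarray(channel_positions)
    d = np.sqrt((p[:, 0] - x) ** 2 + (p[:, 1] - y) ** 2 + z ** 2)
    return k / d


def make_sorting(spike_dict, positions=None, k=None):
    unit_ids = np.array(sorted(spike_dict))
    return SortingGT(unit_ids,
                     {int(u): np.asarray(f, dtype=np.int64)
                      for u, f in spike_dict.items()},
                     positions=positions, k=k)
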