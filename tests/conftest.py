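"""Shared fixtures: small synthetic epochs and datasets, all seeded."""

import numpy as np
import pytest

from optomap.data_model import TraceEpoch

DT_MS = 0.1
PRE_MS = 100.0
POST_MS = 150.0


def make_epoch(voltage=None, fn=None, holding=-70.0, dt_ms=DT_MS, sweep_index=0):
    """Build a TraceEpoch with the standard 100 ms pre / 150 ms post layout.

    ``fn`` maps time (ms relative to stimulus onset) to voltage; ``voltage``
    gives raw samples directly.
    """
    n = int(round((PRE_MS + POST_MS) / dt_ms)) + 1
    onset = int(round(PRE_MS / dt_ms))
    if voltage is None:
        t = (np.arange(n) - onset) * dt_ms
        voltage = np.full(n, holding) if fn is None else holding + fn(t)
    return TraceEpoch(
        sample_interval=dt_ms / 1000.0,
        voltage=np.asarray(voltage, dtype=float),
        stim_onset_index=onset,
        holding_target=holding,
        sweep_index=sweep_index,
    )


def double_exp(t, amplitude, onset_ms, rise=1.5, decay=18.0):
    """Amplitude-normalized difference-of-exponentials PSP at onset_ms."""
    tt = np.maximum(t - onset_ms, 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out = (np.exp(-tt / decay) - np.exp(-tt / rise)) / peak * amplitude
    out[t < onset_ms] = 0.0
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
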