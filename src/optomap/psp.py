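"""PSP quality control, baselining, exponential deconvolution, and metrics.

The central trick is exponential deconvolution of the membrane potential,

    D(t) = V(t) + τ · dV/dt,

which collapses a PSP with decay time constant τ into a brief impulse at
its onset. Peaks of D(t) localize PSP onsets even when successive PSPs
ride on one another's decay, which is what makes paired-pulse ratios
measurable from photostimulus responses. τ defaults to 20 ms (roughly the
membrane time constant of a pyramidal cell); derivative by central
differences with one-sided differences at the edges.

Sign convention: the detection pipeline is polarity-agnostic and works on
depolarizing responses. IPSPs recorded at a −55 mV holding potential are
hyperpolarizing; callers flip the trace sign (``polarity="negative"``)
before detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as scistats

from .data_model import TraceEpoch

#: τ grid searched when adjusting the deconvolution for paired-pulse analysis.
PPR_TAU_GRID_MS = (5.0, 10.0, 15.0, 20.0)


@dataclass
class DeconvolutionParams:
    """Parameters of deconvolution-based PSP detection."""

    tau: float = 20.0  # ms
    threshold_multiple: float = 5.0  # × baseline SD of the deconvolved trace
    search_window: tuple[float, float] = (0.0, 50.0)  # ms after stimulus onset
    baseline_window: float = 20.0  # ms before stimulus onset
    peak_window: float = 20.0  # ms of averaging window after first crossing
    smooth_ms: float = 1.0  # boxcar width applied before the derivative

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class PspMetrics:
    """Summary metrics of one detected PSP."""

    amplitude: float  # mV, peak of the average response in the window
    cv: float  # SD/mean of per-sweep peaks
    rise_20_80: float  # ms, NaN when amplitude <= 0.1 mV
    onset_time: float  # ms from stimulus onset (first threshold crossing)
    n_accepted_sweeps: int
    ppr: float = float("nan")


@dataclass
class PspTrain:
    """Two operator-windowed PSPs within one photoresponse."""

    window_1: tuple[float, float]
    window_2: tuple[float, float]
    peak_1: float
    peak_2: float
    inter_psp_interval: float  # ms between deconvolved peaks
    ppr: float  # peak_2 / peak_1
    tau_used: float  # ms

    #: interval filter applied when pooling PPRs across connections
    POPULATION_INTERVAL_MS = (5.0, 10.0)

    @property
    def in_population_interval(self) -> bool:
        lo, hi = self.POPULATION_INTERVAL_MS
        return lo <= self.inter_psp_interval <= hi


def qc_sweeps(
    epochs: Sequence[TraceEpoch],
    holding_target: float | None = None,
    max_offset_mv: float = 5.0,
    max_drift_mv: float = 1.0,
) -> list[TraceEpoch]:
    """Drop sweeps with an off-target or unstable pre-stimulus baseline.

    A sweep is rejected when the mean voltage in the 50 ms before the
    stimulus differs from the holding target by more than ``max_offset_mv``,
    or when the voltage changes by more than ``max_drift_mv`` within that
    window (assessed as the fitted linear trend across the window, which is
    robust to membrane noise).
    """
    accepted = []
    for epoch in epochs:
        target = epoch.holding_target if holding_target is None else holding_target
        pre = epoch.voltage[epoch.window_slice(-50.0, 0.0)]
        if abs(float(np.mean(pre)) - target) > max_offset_mv:
            continue
        t = np.arange(pre.size) * epoch.dt_ms
        slope = float(np.polyfit(t, pre, 1)[0])
        if abs(slope) * 50.0 > max_drift_mv:
            continue
        accepted.append(epoch)
    return accepted


def baseline_subtract(epoch: TraceEpoch) -> TraceEpoch:
    """Subtract the median potential of the 20 ms pre-stimulus window."""
    base = float(np.median(epoch.voltage[epoch.window_slice(-20.0, 0.0)]))
    return TraceEpoch(
        sample_interval=epoch.sample_interval,
        voltage=epoch.voltage - base,
        stim_onset_index=epoch.stim_onset_index,
        stim_duration=epoch.stim_duration,
        holding_target=epoch.holding_target,
        sweep_index=epoch.sweep_index,
    )


def average_epoch(epochs: Sequence[TraceEpoch]) -> TraceEpoch:
    """Average aligned sweeps into one epoch (sweeps must share timing)."""
    if not epochs:
        raise ValueError("no epochs to average")
    first = epochs[0]
    volts = np.mean([e.voltage for e in epochs], axis=0)
    return TraceEpoch(
        sample_interval=first.sample_interval,
        voltage=volts,
        stim_onset_index=first.stim_onset_index,
        stim_duration=first.stim_duration,
        holding_target=first.holding_target,
    )


def deconvolve(voltage: np.ndarray, tau: float, dt_ms: float) -> np.ndarray:
    """Exponential deconvolution D = V + τ·dV/dt (τ and dt in ms)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    voltage = np.asarray(voltage, dtype=float)
    return voltage + tau * np.gradient(voltage, dt_ms)


def deconvolve_epoch(epoch: TraceEpoch, tau: float, smooth_ms: float = 0.0) -> np.ndarray:
    """Deconvolve one epoch, optionally boxcar-smoothing the trace first.

    Smoothing before the derivative suppresses the high-frequency membrane
    noise that τ·dV/dt would otherwise amplify; the default (no smoothing)
    keeps the operator exact for analytic traces.
    """
    v = epoch.voltage
    if smooth_ms > 0:
        width = max(int(round(smooth_ms / epoch.dt_ms)), 1)
        if width > 1:
            kernel = np.ones(width) / width
            pad = width // 2
            padded = np.pad(v, pad, mode="edge")
            v = np.convolve(padded, kernel, mode="same")[pad : pad + v.size]
    return deconvolve(v, tau, epoch.dt_ms)


def detect_psp_window(
    average: TraceEpoch,
    params: DeconvolutionParams | None = None,
) -> list[tuple[float, float]]:
    """Find PSP measurement window(s) on a baselined average trace.

    Peaks of the deconvolved trace within the post-stimulus search window
    are compared to a threshold of ``threshold_multiple`` × the SD of the
    deconvolved trace in the pre-stimulus baseline window. A single
    supra-threshold peak yields the window [first crossing, +20 ms]; with
    multiple peaks each window is truncated at the inter-peak minimum of
    the deconvolved trace. Times are ms relative to stimulus onset.
    """
    params = params or DeconvolutionParams()
    dec = deconvolve_epoch(average, params.tau, params.smooth_ms)
    base = dec[average.window_slice(-params.baseline_window, 0.0)]
    thr = params.threshold_multiple * float(np.std(base))
    lo_ms, hi_ms = params.search_window
    search = average.window_slice(lo_ms, hi_ms)
    seg = dec[search]
    dt = average.dt_ms
    peaks, _ = sps.find_peaks(seg, height=thr, distance=max(int(2.0 / dt), 1))
    # merge peaks without a genuine valley between them (residual noise
    # wiggles on one PSP's rise must not split its window)
    merged_peaks: list[int] = []
    for pk in peaks:
        if merged_peaks:
            prev = merged_peaks[-1]
            valley = float(np.min(seg[prev : pk + 1]))
            if valley > 0.5 * min(seg[prev], seg[pk]):
                if seg[pk] > seg[prev]:
                    merged_peaks[-1] = int(pk)
                continue
        merged_peaks.append(int(pk))
    peaks = np.asarray(merged_peaks)
    if peaks.size == 0:
        return []
    windows = []
    for k, pk in enumerate(peaks):
        # first threshold crossing on this peak's rise
        i = pk
        while i > 0 and seg[i - 1] > thr:
            i -= 1
        start = lo_ms + i * dt
        stop = start + params.peak_window
        if k + 1 < peaks.size:
            valley = int(pk + np.argmin(seg[pk : peaks[k + 1] + 1]))
            stop = min(stop, lo_ms + valley * dt)
        if k > 0:
            prev = peaks[k - 1]
            valley = int(prev + np.argmin(seg[prev : pk + 1]))
            start = max(start, lo_ms + valley * dt)
        windows.append((start, min(stop, hi_ms)))
    # merge windows that collapsed onto the same crossing (shared rise)
    merged: list[tuple[float, float]] = []
    for win in windows:
        if merged and win[0] <= merged[-1][0] + dt / 2:
            merged[-1] = (merged[-1][0], max(merged[-1][1], win[1]))
        else:
            merged.append(win)
    return merged


def measure_amplitude_cv(
    epochs: Sequence[TraceEpoch],
    window: tuple[float, float],
) -> tuple[float, float]:
    """Amplitude (peak of the average in the window) and CV of per-sweep peaks."""
    if not epochs:
        raise ValueError("no epochs")
    avg = average_epoch(epochs)
    sl = avg.window_slice(*window)
    if sl.start >= sl.stop:
        return float("nan"), float("nan")
    amplitude = float(np.max(avg.voltage[sl]))
    per_sweep = np.array([float(np.max(e.voltage[sl])) for e in epochs])
    mean = float(np.mean(per_sweep))
    cv = float(np.std(per_sweep, ddof=0) / mean) if mean != 0 else float("nan")
    return amplitude, cv


def rise_time(
    average: TraceEpoch,
    window: tuple[float, float],
    min_amplitude: float = 0.1,
) -> float:
    """20–80% rise time (ms) of the average response in the window.

    Crossing times are linearly interpolated between samples. Responses at
    or below ``min_amplitude`` mV return NaN (too easily contaminated by
    spontaneous background activity to report).
    """
    sl = average.window_slice(*window)
    seg = average.voltage[sl]
    if seg.size < 2:
        return float("nan")
    ipk = int(np.argmax(seg))
    peak = float(seg[ipk])
    if peak <= min_amplitude:
        return float("nan")

    def crossing(level: float) -> float:
        idx = np.nonzero(seg[: ipk + 1] >= level)[0]
        i = int(idx[0]) if idx.size else ipk
        if i == 0:
            return 0.0
        frac = (level - seg[i - 1]) / (seg[i] - seg[i - 1])
        return (i - 1 + frac) * average.dt_ms

    return crossing(0.8 * peak) - crossing(0.2 * peak)


def _select_tau(
    average: TraceEpoch, window_2: tuple[float, float], smooth_ms: float = 1.0
) -> float:
    """Pick τ from the grid minimizing baseline overshoot after the 2nd PSP.

    The criterion is the smallest |mean of the deconvolved trace| in a
    10 ms window following the second window's deconvolved peak — the
    automated version of adjusting τ "to avoid overshoot or undershoot".
    """
    best_tau, best_score = PPR_TAU_GRID_MS[-1], np.inf
    for tau in PPR_TAU_GRID_MS:
        dec = deconvolve_epoch(average, tau, smooth_ms)
        sl2 = average.window_slice(*window_2)
        pk = sl2.start + int(np.argmax(dec[sl2]))
        tail = dec[pk : pk + int(round(10.0 / average.dt_ms))]
        score = abs(float(np.mean(tail))) if tail.size else np.inf
        if score < best_score:
            best_tau, best_score = tau, score
    return best_tau


def paired_pulse_ratio(
    epochs: Sequence[TraceEpoch],
    window_1: tuple[float, float],
    window_2: tuple[float, float],
    tau: float | None = None,
    smooth_ms: float = 1.0,
) -> PspTrain:
    """Paired-pulse ratio from two operator-set non-overlapping windows.

    Each sweep is exponentially deconvolved (accounting for temporal
    summation of the second PSP on the first's decay); the deconvolved
    peak within each window is averaged across sweeps and the PPR reported
    as second/first. When ``tau`` is None it is chosen from
    :data:`PPR_TAU_GRID_MS` by :func:`_select_tau`.
    """
    if window_1[1] > window_2[0]:
        raise ValueError("windows must be non-overlapping and ordered")
    avg = average_epoch(epochs)
    tau_used = float(tau) if tau is not None else _select_tau(avg, window_2, smooth_ms)

    peaks1, peaks2 = [], []
    for e in epochs:
        dec = deconvolve_epoch(e, tau_used, smooth_ms)
        peaks1.append(float(np.max(dec[e.window_slice(*window_1)])))
        peaks2.append(float(np.max(dec[e.window_slice(*window_2)])))
    peak_1 = float(np.mean(peaks1))
    peak_2 = float(np.mean(peaks2))

    dec_avg = deconvolve_epoch(avg, tau_used, smooth_ms)
    sl1, sl2 = avg.window_slice(*window_1), avg.window_slice(*window_2)
    t1 = (sl1.start + int(np.argmax(dec_avg[sl1])) - avg.stim_onset_index) * avg.dt_ms
    t2 = (sl2.start + int(np.argmax(dec_avg[sl2])) - avg.stim_onset_index) * avg.dt_ms

    ppr = peak_2 / peak_1 if peak_1 > 0 else float("nan")
    return PspTrain(
        window_1=window_1,
        window_2=window_2,
        peak_1=peak_1,
        peak_2=peak_2,
        inter_psp_interval=t2 - t1,
        ppr=ppr,
        tau_used=tau_used,
    )


def rundown(amplitudes: Sequence[float]) -> float:
    """Amplitude trend over repeated stimulation, % of mean per stimulus.

    Ordinary least-squares slope of amplitude versus stimulus number,
    normalized to the mean amplitude.
    """
    amps = np.asarray(amplitudes, dtype=float)
    amps = amps[np.isfinite(amps)]
    if amps.size < 5:
        raise ValueError("need >=5 sweeps with defined peaks")
    slope = scistats.linregress(np.arange(amps.size), amps).slope
    mean = float(np.mean(amps))
    return float(100.0 * slope / mean) if mean != 0 else float("nan")


def analyze_pair(
    epochs: Sequence[TraceEpoch],
    polarity: str = "positive",
    params: DeconvolutionParams | None = None,
) -> PspMetrics | None:
    """QC, baseline, detect, and measure one probed pair's response set.

    ``polarity="negative"`` flips traces before detection (IPSPs at a
    depolarized holding potential). Returns None when no sweep survives QC
    or no window is detected.
    """
    accepted = qc_sweeps(epochs)
    if not accepted:
        return None
    baselined = [baseline_subtract(e) for e in accepted]
    if polarity == "negative":
        for b in baselined:
            b.voltage = -b.voltage
    avg = average_epoch(baselined)
    windows = detect_psp_window(avg, params)
    if not windows:
        return None
    amplitude, cv = measure_amplitude_cv(baselined, windows[0])
    return PspMetrics(
        amplitude=amplitude,
        cv=cv,
        rise_20_80=rise_time(avg, windows[0]),
        onset_time=windows[0][0],
        n_accepted_sweeps=len(accepted),
    )
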