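"""Intrinsic electrophysiology features and interneuron classification.

Extracts the standard 14-feature intrinsic characterization from a family
of 1 s square current steps (−130…250 pA in 20 pA steps from a −70 mV
baseline) and clusters interneurons into fast-spiking (putative Pvalb),
putative VIP, and putative Sst classes. Membrane time constant fits
exclude the weakest hyperpolarizing step (too easily corrupted by
background synaptic activity); AP waveform features come from the first
spike at rheobase; rate and adaptation from the step 40 pA above
rheobase.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .data_model import TraceEpoch

INTERNEURON_CLASSES = ("FSI", "putative VIP", "putative Sst")


@dataclass
class IntrinsicFeatures:
    """The 14 intrinsic features used for subclass assignment."""

    v_rest: float  # mV
    input_resistance: float  # MΩ
    tau: float  # ms
    capacitance: float  # pF (= tau / input_resistance)
    sag: float  # (peak − steady state) / peak on the −130 pA step
    rheobase: float  # pA
    ap_fwhm: float  # ms
    upstroke_downstroke_ratio: float
    ap_peak: float  # mV
    ap_trough: float  # mV
    ap_height: float  # mV (= peak − trough)
    avg_firing_rate: float  # Hz at rheobase + 40 pA
    adaptation: float  # adaptation index at rheobase + 40 pA
    f_i_slope: float  # spikes/s/pA

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def _spike_indices(v: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    above = v >= threshold
    return np.nonzero(above[1:] & ~above[:-1])[0] + 1


def _step_segments(sweep: TraceEpoch) -> tuple[np.ndarray, np.ndarray]:
    """(baseline samples, step samples) of one current-step sweep."""
    on = sweep.stim_onset_index
    off = on + int(round(sweep.stim_duration / sweep.dt_ms))
    return sweep.voltage[:on], sweep.voltage[on:off]


def extract_intrinsic(
    sweeps: Sequence[tuple[float, TraceEpoch]],
) -> IntrinsicFeatures:
    """Extract the 14 intrinsic features from a current-step sweep family.

    ``sweeps`` is a list of (current_pA, epoch); AP features are NaN when
    no step reaches threshold.
    """
    sweeps = sorted(sweeps, key=lambda s: s[0])
    currents = np.array([c for c, _ in sweeps])
    v_rest = float(np.mean([np.mean(_step_segments(e)[0]) for _, e in sweeps]))

    # subthreshold passive properties from hyperpolarizing steps
    hyper = [(c, e) for c, e in sweeps if c < 0]
    if len(hyper) >= 2:
        hyper_used = hyper[:-1]  # exclude the weakest (closest to 0)
    else:
        hyper_used = hyper
    deflections, taus = [], []
    for c, e in hyper_used:
        base, step = _step_segments(e)
        b = float(np.mean(base))
        ss = float(np.mean(step[-int(100.0 / e.dt_ms):])) - b
        deflections.append((c, ss))
        # fit the charging phase up to the (most hyperpolarized) extreme
        i_peak = int(np.argmin(step))
        t = np.arange(i_peak + 1) * e.dt_ms
        y = step[: i_peak + 1] - b
        try:
            (amp, tau_fit), _ = curve_fit(
                lambda tt, a, tau: a * (1.0 - np.exp(-tt / tau)),
                t,
                y,
                p0=[y[-1], 15.0],
                maxfev=5000,
            )
            taus.append(abs(tau_fit))
        except RuntimeError:
            pass
    if len(deflections) >= 2:
        cs = np.array([c for c, _ in deflections])
        ds = np.array([d for _, d in deflections])
        r_in = float(np.polyfit(cs, ds, 1)[0] * 1e3)  # mV/pA = GΩ → MΩ
    elif deflections:
        c, d = deflections[0]
        r_in = float(d / c * 1e3)
    else:
        r_in = float("nan")
    tau = float(np.mean(taus)) if taus else float("nan")
    capacitance = tau / r_in * 1e3 if np.isfinite(tau) and r_in > 0 else float("nan")

    # sag on the −130 pA (most hyperpolarized) step
    sag = float("nan")
    if hyper:
        c, e = hyper[0]
        base, step = _step_segments(e)
        b = float(np.mean(base))
        peak = float(np.min(step)) - b
        ss = float(np.mean(step[-int(100.0 / e.dt_ms):])) - b
        sag = (peak - ss) / peak if peak != 0 else float("nan")

    # spiking sweeps
    rates = []
    rheobase = float("nan")
    for c, e in sweeps:
        if c <= 0:
            continue
        _, step = _step_segments(e)
        spikes = _spike_indices(step)
        if spikes.size and np.isnan(rheobase):
            rheobase = float(c)
        if spikes.size:
            rates.append((c, spikes.size / (e.stim_duration / 1000.0)))

    ap_feats = dict.fromkeys(
        ["ap_fwhm", "upstroke_downstroke_ratio", "ap_peak", "ap_trough", "ap_height"],
        float("nan"),
    )
    avg_rate = adaptation = f_i_slope = float("nan")
    if np.isfinite(rheobase):
        e = dict((c, e) for c, e in sweeps)[rheobase]
        _, step = _step_segments(e)
        ap_feats = _ap_features(step, e.dt_ms)
        # rate/adaptation from the step closest to rheobase + 40 pA
        supra = np.array([c for c, _ in rates])
        target = rheobase + 40.0
        c_use = supra[np.argmin(np.abs(supra - target))]
        e40 = dict((c, e) for c, e in sweeps)[float(c_use)]
        _, step40 = _step_segments(e40)
        spikes40 = _spike_indices(step40)
        avg_rate = spikes40.size / (e40.stim_duration / 1000.0)
        if spikes40.size >= 3:
            isi = np.diff(spikes40) * e40.dt_ms
            adaptation = float(np.mean((isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])))
        elif spikes40.size == 2:
            adaptation = 0.0
        if len(rates) >= 2:
            cs = np.array([c for c, _ in rates])
            rs = np.array([r for _, r in rates])
            f_i_slope = float(np.polyfit(cs, rs, 1)[0])

    return IntrinsicFeatures(
        v_rest=v_rest,
        input_resistance=r_in,
        tau=tau,
        capacitance=capacitance,
        sag=sag,
        rheobase=rheobase,
        avg_firing_rate=avg_rate,
        adaptation=adaptation,
        f_i_slope=f_i_slope,
        **ap_feats,
    )


def _ap_features(step: np.ndarray, dt_ms: float) -> dict[str, float]:
    """Waveform features of the first AP in a suprathreshold step."""
    spikes = _spike_indices(step)
    if spikes.size == 0:
        return dict.fromkeys(
            ["ap_fwhm", "upstroke_downstroke_ratio", "ap_peak", "ap_trough",
             "ap_height"],
            float("nan"),
        )
    i0 = spikes[0]
    stop = spikes[1] if spikes.size > 1 else min(i0 + int(10.0 / dt_ms), step.size)
    # search back from the crossing for the AP threshold (dV/dt > 20 mV/ms)
    dvdt = np.gradient(step, dt_ms)
    i_start = i0
    while i_start > 0 and dvdt[i_start - 1] > 20.0:
        i_start -= 1
    seg = step[i_start:stop]
    d_seg = dvdt[i_start:stop]
    i_pk = int(np.argmax(seg))
    peak = float(seg[i_pk])
    trough = float(np.min(seg[i_pk:])) if i_pk < seg.size else float(np.min(seg))
    thr = float(seg[0])
    half = thr + 0.5 * (peak - thr)
    above = seg >= half
    fwhm = float(np.sum(above) * dt_ms)
    up = float(np.max(d_seg))
    down = float(np.min(d_seg))
    ratio = up / abs(down) if down != 0 else float("nan")
    return {
        "ap_fwhm": fwhm,
        "upstroke_downstroke_ratio": ratio,
        "ap_peak": peak,
        "ap_trough": trough,
        "ap_height": peak - trough,
    }


def cluster_interneurons(
    features: pd.DataFrame,
    seed: int = 0,
    method: str = "gmm",
) -> pd.Series:
    """Cluster interneurons into FSI / putative VIP / putative Sst.

    Features are z-scored and fit with a 3-component Gaussian mixture
    (diagonal covariance — stable for the few tens of cells per class a
    mapping study records; 10 restarts, fixed seed); ``method="ward"``
    switches to agglomerative Ward linkage. Components map to labels by
    canonical signatures: FSI = narrowest AP FWHM, then putative Sst =
    larger sag, putative VIP = the remainder (highest input resistance).
    """
    if len(features) < 3:
        raise ValueError("need at least as many cells as clusters")
    X = StandardScaler().fit_transform(features[IntrinsicFeatures.names()].to_numpy())
    if method == "gmm":
        model = GaussianMixture(
            n_components=3,
            covariance_type="diag",
            n_init=10,
            random_state=seed,
            reg_covar=1e-3,
        )
        # fit on canonically sorted rows so the result is invariant to the
        # order cells were recorded in; assign by per-row prediction
        model.fit(X[np.lexsort(X.T)])
        assignments = model.predict(X)
    elif method == "ward":
        from sklearn.cluster import AgglomerativeClustering

        assignments = AgglomerativeClustering(n_clusters=3, linkage="ward").fit_predict(X)
    else:
        raise ValueError(f"unknown method {method!r}")

    means = features.groupby(assignments).mean(numeric_only=True)
    labels = {}
    fsi = means["ap_fwhm"].idxmin()
    labels[fsi] = "FSI"
    rest = [k for k in means.index if k != fsi]
    sst = means.loc[rest, "sag"].idxmax()
    labels[sst] = "putative Sst"
    vip = [k for k in rest if k != sst][0]
    labels[vip] = "putative VIP"
    return pd.Series([labels[a] for a in assignments], index=features.index, name="class")
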