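"""Photostimulus characterization from loose-seal spike-outcome tables.

Covers the quantities used to calibrate mapping experiments: the minimum
power driving spiking on 10/10 trials, first-spike latency and its jitter,
and the lateral/axial spatial resolution obtained from Gaussian fits of
spike probability versus photostimulus offset. FWHM = 2·sqrt(2·ln 2)·σ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

#: FWHM of a Gaussian with unit σ.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Sentinel σ for degenerate (non-decaying) profiles.
SIGMA_UNDEFINED = float("inf")

#: Columns of a spike-outcome table.
SPIKE_OUTCOME_COLUMNS = [
    "cell_id",
    "power_mw",
    "lateral_offset_um",
    "axial_offset_um",
    "trial_index",
    "spike_times_ms",
]


@dataclass
class ResolutionProfile:
    """Gaussian lateral/axial activation-probability model of the photostimulus."""

    sigma_lateral: float  # µm
    sigma_axial: float  # µm
    peak_probability: float = 1.0

    @property
    def fwhm_lateral(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_lateral

    @property
    def fwhm_axial(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_axial

    def lateral_probability(self, offset_um) -> np.ndarray:
        return self.peak_probability * np.exp(
            -np.square(offset_um) / (2.0 * self.sigma_lateral**2)
        )

    def axial_probability(self, offset_um) -> np.ndarray:
        return self.peak_probability * np.exp(
            -np.square(offset_um) / (2.0 * self.sigma_axial**2)
        )

    @classmethod
    def from_fwhm(
        cls, fwhm_lateral: float, fwhm_axial: float, peak_probability: float = 1.0
    ) -> "ResolutionProfile":
        return cls(
            sigma_lateral=fwhm_lateral / FWHM_PER_SIGMA,
            sigma_axial=fwhm_axial / FWHM_PER_SIGMA,
            peak_probability=peak_probability,
        )


def min_reliable_power(
    powers_mw: Sequence[float], spiked: Sequence[Sequence[bool]]
) -> float:
    """Smallest tested power with spiking on every trial (NaN when absent).

    ``spiked[i]`` holds the per-trial spike outcomes at ``powers_mw[i]``;
    the rule is strict — 9/10 does not qualify.
    """
    order = np.argsort(np.asarray(powers_mw, dtype=float))
    for i in order:
        outcomes = list(spiked[i])
        if outcomes and all(outcomes):
            return float(powers_mw[i])
    return float("nan")


def latency_jitter(
    spike_times_by_trial: Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Mean first-spike latency and its jitter (sample SD, n−1) in ms.

    Trials without spikes are ignored; jitter is NaN with fewer than two
    spiking trials.
    """
    firsts = [min(t) for t in spike_times_by_trial if len(t) > 0]
    if not firsts:
        return float("nan"), float("nan")
    mean = float(np.mean(firsts))
    jitter = float(np.std(firsts, ddof=1)) if len(firsts) >= 2 else float("nan")
    return mean, jitter


def fit_gaussian_axis(
    offsets_um: Sequence[float], probabilities: Sequence[float]
) -> tuple[float, float]:
    """Least-squares fit of p(d) = A·exp(−d²/2σ²), A ∈ (0, 1].

    Returns (sigma, amplitude). The fit is centered on zero offset with no
    baseline term. A profile that does not decrease with offset triggers a
    warning and the σ → ∞ sentinel.
    """
    d = np.asarray(offsets_um, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if d.size < 3 or 0.0 not in np.round(np.abs(d), 9):
        raise ValueError("need probabilities at >=3 offsets including 0")

    order = np.argsort(np.abs(d))
    if np.all(np.diff(p[order]) >= 0) and p.std() == 0:
        warnings.warn("spike probability does not decrease with offset", stacklevel=2)
        return SIGMA_UNDEFINED, float(p.max())

    def model(x, a, sigma):
        return a * np.exp(-np.square(x) / (2.0 * sigma**2))

    try:
        (a, sigma), _ = curve_fit(
            model,
            d,
            p,
            p0=[max(p.max(), 1e-3), max(np.abs(d).max() / 2.0, 1.0)],
            bounds=([1e-6, 1e-6], [1.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        warnings.warn("Gaussian resolution fit did not converge", stacklevel=2)
        return SIGMA_UNDEFINED, float(p.max())
    if not np.all(np.diff(p[order]) <= 0) and np.ptp(p) < 1e-12:
        warnings.warn("spike probability does not decrease with offset", stacklevel=2)
    return float(abs(sigma)), float(a)


def spike_probability_by_distance(
    offsets_um: Sequence[float], spiked: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse trials to spike probability per |offset| (spokes averaged)."""
    frame = pd.DataFrame(
        {"d": np.abs(np.asarray(offsets_um, dtype=float)), "s": np.asarray(spiked, bool)}
    )
    grouped = frame.groupby("d")["s"].mean()
    return grouped.index.to_numpy(), grouped.to_numpy()


def fit_gaussian_resolution(outcomes: pd.DataFrame) -> ResolutionProfile:
    """Fit lateral and axial Gaussian resolution from a spike-outcome table.

    ``outcomes`` carries one row per trial with ``lateral_offset_um``,
    ``axial_offset_um`` and a boolean ``spiked`` column; per-axis fits use
    trials where the other offset is zero, with radial-grid spokes averaged
    per distance.
    """
    lat = outcomes[outcomes["axial_offset_um"] == 0]
    ax = outcomes[outcomes["lateral_offset_um"] == 0]
    d_lat, p_lat = spike_probability_by_distance(
        lat["lateral_offset_um"], lat["spiked"]
    )
    d_ax, p_ax = spike_probability_by_distance(ax["axial_offset_um"], ax["spiked"])
    sig_lat, a_lat = fit_gaussian_axis(d_lat, p_lat)
    sig_ax, a_ax = fit_gaussian_axis(d_ax, p_ax)
    return ResolutionProfile(
        sigma_lateral=sig_lat,
        sigma_axial=sig_ax,
        peak_probability=float(min(max(a_lat, a_ax), 1.0)),
    )


def depth_power_correlation(
    depths_um: Sequence[float], min_powers_mw: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between cell depth and minimum reliable power."""
    d = np.asarray(depths_um, dtype=float)
    p = np.asarray(min_powers_mw, dtype=float)
    ok = np.isfinite(d) & np.isfinite(p)
    r, pval = pearsonr(d[ok], p[ok])
    return float(r), float(pval)
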