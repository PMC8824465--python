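"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analysis
assumes: quantal (binomial-release) PSP amplitude variability with its
inverse CV–amplitude relation, log-normal-ish photostimulation
sensitivity with sub-millisecond latency jitter and Gaussian lateral /
axial activation falloff, distance-dependent connectivity, direct
stimulation artifacts in opsin-positive patched cells, Poisson
spontaneous background PSPs, and Ornstein–Uhlenbeck membrane noise.

All randomness flows from one integer seed via named substreams
(:func:`substream`), so each generator stage is independently
reproducible and adding sweeps to one pair never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .data_model import (
    CONNECTED,
    NOT_CONNECTED,
    CellRecord,
    ConnectivityDataset,
    ExperimentRecord,
    PairGeometry,
    ProbedConnection,
    TraceEpoch,
)
from .offtarget import CellMapVolume


def substream(seed: int, *labels) -> np.random.Generator:
    """Derive a named, reproducible random stream from the master seed."""
    key = zlib.crc32("/".join(str(x) for x in labels).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


# --------------------------------------------------------------------------
# parameter models


@dataclass
class QuantalSynapseParams:
    """Binomial quantal-release synapse.

    Mean amplitude = n_sites · release_prob · quantal_size;
    CV = sqrt((1 − release_prob) / (n_sites · release_prob)).
    """

    n_sites: int = 5
    release_prob: float = 0.5
    quantal_size: float = 0.1  # mV
    rise_tau: float = 1.5  # ms
    decay_tau: float = 18.0  # ms
    synaptic_latency: float = 1.5  # ms from presynaptic spike

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.release_prob <= 1.0:
            raise ValueError("release_prob must be in [0, 1]")
        if self.decay_tau <= self.rise_tau:
            raise ValueError("decay_tau must exceed rise_tau")

    @property
    def mean_amplitude(self) -> float:
        return self.n_sites * self.release_prob * self.quantal_size

    @property
    def cv(self) -> float:
        return float(
            np.sqrt((1.0 - self.release_prob) / (self.n_sites * self.release_prob))
        )


@dataclass
class SpikingModel:
    """Photo-evoked spiking of one opsin-expressing cell.

    Spike probability at zero offset (and power ≥ min_reliable_power) is 1
    and falls off as the product of lateral and axial Gaussians.
    """

    min_reliable_power: float = 20.0  # mW
    latency_mean: float = 5.0  # ms from stimulus onset
    jitter_sd: float = 0.5  # ms
    n_spikes_probs: tuple[float, ...] = (0.8, 0.15, 0.05)  # P(1), P(2), P(3) spikes
    lateral_sigma: float = 8.0  # µm
    axial_sigma: float = 22.0  # µm
    extra_spike_interval: float = 7.0  # ms between successive spikes

    def spike_probability(self, power_mw: float, lateral_um: float, axial_um: float):
        on_target = 1.0 if power_mw >= self.min_reliable_power else 0.0
        return on_target * np.exp(
            -(np.square(lateral_um) / (2 * self.lateral_sigma**2))
            - (np.square(axial_um) / (2 * self.axial_sigma**2))
        )


@dataclass
class NoiseModel:
    """Membrane noise, spontaneous PSPs, and the direct-stimulation artifact."""

    baseline_sd: float = 0.1  # mV, OU process
    correlation_time: float = 5.0  # ms
    spontaneous_psp_rate: float = 0.2  # Hz
    spontaneous_amplitude_scale: float = 0.2  # mV, exponential scale
    artifact_amplitude: float = 0.23  # mV, opsin-positive patched cells


# --------------------------------------------------------------------------
# low-level building blocks


def psp_kernel(
    t_ms: np.ndarray, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Amplitude-normalized difference-of-exponentials PSP waveform."""
    if decay_tau <= rise_tau:
        raise ValueError("decay_tau must exceed rise_tau")
    t = np.maximum(np.asarray(t_ms, dtype=float), 0.0)
    shape = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    t_peak = (
        rise_tau
        * decay_tau
        / (decay_tau - rise_tau)
        * np.log(decay_tau / rise_tau)
    )
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    out = shape / peak
    out[np.asarray(t_ms) < 0] = 0.0
    return out


def ou_noise(
    rng: np.random.Generator, n: int, dt_ms: float, sd: float, tau_ms: float
) -> np.ndarray:
    """Ornstein–Uhlenbeck noise with stationary SD ``sd``, exact update."""
    if sd == 0:
        return np.zeros(n)
    alpha = np.exp(-dt_ms / tau_ms)
    innov_sd = sd * np.sqrt(1.0 - alpha**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -alpha], eps)


# --------------------------------------------------------------------------
# generators


def gen_cell_map(
    density: float | dict[str, float],
    bounds: tuple[tuple[float, float], ...],
    seed: int,
) -> CellMapVolume:
    """Homogeneous Poisson point process of labeled cells in a µm box.

    ``density`` is cells/mm³ — a scalar for the whole volume or a mapping
    from layer label to density, with layers stacked along the y (pia)
    axis of ``bounds``.
    """
    rng = substream(seed, "cell_map")
    (x0, x1), (y0, y1), (z0, z1) = bounds
    for lo, hi in bounds:
        if not hi > lo:
            raise ValueError("degenerate bounds")

    def draw_slab(dens: float, ylo: float, yhi: float) -> np.ndarray:
        if dens < 0:
            raise ValueError("density must be >= 0")
        vol_mm3 = (x1 - x0) * (yhi - ylo) * (z1 - z0) * 1e-9
        n = rng.poisson(dens * vol_mm3)
        pts = np.column_stack(
            [
                rng.uniform(x0, x1, n),
                rng.uniform(ylo, yhi, n),
                rng.uniform(z0, z1, n),
            ]
        )
        return pts

    if isinstance(density, dict):
        from .data_model import LAYER_BOUNDARIES

        slabs = []
        for label, lo, hi in LAYER_BOUNDARIES:
            if label not in density:
                continue
            ylo, yhi = max(lo, y0), min(hi, y1)
            if yhi > ylo:
                slabs.append(draw_slab(density[label], ylo, yhi))
        pts = np.vstack(slabs) if slabs else np.empty((0, 3))
    else:
        pts = draw_slab(float(density), y0, y1)
    return CellMapVolume(positions=pts, bounds=bounds)


def gen_network(
    cell_map: CellMapVolume,
    patched_positions: np.ndarray,
    kernel: Callable[[np.ndarray], np.ndarray],
    seed: int,
) -> np.ndarray:
    """Ground-truth adjacency: independent Bernoulli per ordered pair.

    ``kernel`` maps 3D intersomatic distance (µm) to connection
    probability; returns a boolean (n_cells, n_patched) array.
    """
    rng = substream(seed, "network")
    patched = np.asarray(patched_positions, dtype=float).reshape(-1, 3)
    if cell_map.n_cells == 0 or patched.shape[0] == 0:
        return np.zeros((cell_map.n_cells, patched.shape[0]), dtype=bool)
    d = np.linalg.norm(
        cell_map.positions[:, None, :] - patched[None, :, :], axis=-1
    )
    p = np.asarray(kernel(d), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("kernel must return probabilities in [0, 1]")
    return rng.random(p.shape) < p


@dataclass
class PhotoresponseTruth:
    """Ground truth recorded alongside generated sweeps."""

    connected: bool
    mean_amplitude: float
    cv: float
    onset_latency: float  # ms, spike latency + synaptic latency
    spike_times: list[list[float]] = field(default_factory=list)
    quantal_contents: list[list[int]] = field(default_factory=list)


def gen_photoresponse(
    connection: QuantalSynapseParams | None,
    spiking: SpikingModel,
    noise: NoiseModel,
    n_sweeps: int,
    seed: int,
    pre_ms: float = 100.0,
    post_ms: float = 150.0,
    dt_ms: float = 0.1,
    holding_target: float = -70.0,
    opsin_positive_post: bool = False,
    polarity: int = 1,
) -> tuple[list[TraceEpoch], PhotoresponseTruth]:
    """Photostimulus-evoked current-clamp sweeps for one probed pair.

    Per sweep, a sampled spike count and spike times drive
    difference-of-exponential PSPs with binomially sampled quantal
    content, superposed on OU noise and Poisson spontaneous events.
    ``connection=None`` yields noise-only traces. ``polarity=-1``
    generates hyperpolarizing (inhibitory) responses.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = substream(seed, "photoresponse")
    n_samples = int(round((pre_ms + post_ms) / dt_ms)) + 1
    onset_idx = int(round(pre_ms / dt_ms))
    t_rel = (np.arange(n_samples) - onset_idx) * dt_ms

    truth = PhotoresponseTruth(
        connected=connection is not None,
        mean_amplitude=connection.mean_amplitude if connection else 0.0,
        cv=connection.cv if connection else float("nan"),
        onset_latency=(
            spiking.latency_mean + connection.synaptic_latency
            if connection
            else float("nan")
        ),
    )

    epochs = []
    for sweep in range(n_sweeps):
        v = np.full(n_samples, float(holding_target))
        v += ou_noise(rng, n_samples, dt_ms, noise.baseline_sd, noise.correlation_time)

        # spontaneous PSPs, Poisson in time over the whole sweep
        if noise.spontaneous_psp_rate > 0:
            duration_s = (pre_ms + post_ms) / 1000.0
            for _ in range(rng.poisson(noise.spontaneous_psp_rate * duration_s)):
                t0 = rng.uniform(-pre_ms, post_ms)
                amp = rng.exponential(noise.spontaneous_amplitude_scale)
                v += amp * psp_kernel(t_rel - t0, 1.5, 18.0)

        spike_times: list[float] = []
        contents: list[int] = []
        if connection is not None:
            n_spk = 1 + rng.choice(
                len(spiking.n_spikes_probs), p=np.asarray(spiking.n_spikes_probs)
            )
            t_spk = spiking.latency_mean + rng.normal(0.0, spiking.jitter_sd)
            for k in range(n_spk):
                spike_times.append(t_spk + k * spiking.extra_spike_interval)
            for t0 in spike_times:
                k_quanta = int(
                    rng.binomial(connection.n_sites, connection.release_prob)
                )
                contents.append(k_quanta)
                amp = k_quanta * connection.quantal_size
                v += polarity * amp * psp_kernel(
                    t_rel - (t0 + connection.synaptic_latency),
                    connection.rise_tau,
                    connection.decay_tau,
                )

        # direct artifact: depolarization coincident with stimulus onset
        if opsin_positive_post and noise.artifact_amplitude > 0:
            v += noise.artifact_amplitude * psp_kernel(t_rel, 0.5, 12.0)

        truth.spike_times.append(spike_times)
        truth.quantal_contents.append(contents)
        epochs.append(
            TraceEpoch(
                sample_interval=dt_ms / 1000.0,
                voltage=v,
                stim_onset_index=onset_idx,
                stim_duration=10.0,
                holding_target=holding_target,
                sweep_index=sweep,
            )
        )
    return epochs, truth


# --------------------------------------------------------------------------
# intrinsic current-step sweeps


@dataclass
class CellClassParams:
    """Generating parameters of a leaky-integrate-and-fire-with-adaptation cell."""

    v_rest: float = -72.8  # mV
    input_resistance: float = 90.0  # MΩ
    tau: float = 14.4  # ms
    sag: float = 0.0  # (peak − steady state) / peak on the −130 pA step
    rheobase: float = 170.0  # pA
    f_i_slope: float = 0.12  # spikes/s/pA above rheobase
    rate_at_rheobase: float = 2.0  # spikes/s
    adaptation: float = 0.0  # adaptation index; ISI ratio (1+A)/(1−A)
    ap_peak: float = 40.0  # mV
    ap_trough: float = -48.0  # mV
    ap_fwhm: float = 1.4  # ms
    upstroke_downstroke_ratio: float = 4.3
    ap_threshold: float = -40.0  # mV


def _insert_ap(
    v: np.ndarray, t_idx: int, dt_ms: float, p: CellClassParams
) -> None:
    """Overwrite samples with a piecewise-linear AP waveform at t_idx."""
    amp = p.ap_peak - p.ap_threshold
    # FWHM at half height between threshold and peak, split by up/down slopes
    down = amp * (1.0 + p.upstroke_downstroke_ratio) / (
        2.0 * p.upstroke_downstroke_ratio * p.ap_fwhm
    )
    up = p.upstroke_downstroke_ratio * down
    n_up = max(int(round(amp / up / dt_ms)), 1)
    n_down = max(int(round((p.ap_peak - p.ap_trough) / down / dt_ms)), 2)
    n_rec = max(int(round(2.0 / dt_ms)), 1)  # 2 ms recovery to threshold
    i = t_idx
    for k in range(n_up):
        if i >= v.size:
            return
        v[i] = p.ap_threshold + amp * (k + 1) / n_up
        i += 1
    for k in range(n_down):
        if i >= v.size:
            return
        v[i] = p.ap_peak - (p.ap_peak - p.ap_trough) * (k + 1) / n_down
        i += 1
    for k in range(n_rec):
        if i >= v.size:
            return
        v[i] = p.ap_trough + (p.ap_threshold - 5.0 - p.ap_trough) * (k + 1) / n_rec
        i += 1


def gen_intrinsic_sweeps(
    cell_class_params: CellClassParams,
    current_steps: Sequence[float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    dt_ms: float = 0.1,
    step_ms: float = 1000.0,
    pre_ms: float = 200.0,
    post_ms: float = 300.0,
) -> list[tuple[float, TraceEpoch]]:
    """Current-step sweep family (default −130…250 pA in 20 pA steps).

    Subthreshold responses follow RC charging toward I·R with the cell's
    time constant (plus an optional sag relaxation on hyperpolarizing
    steps); suprathreshold steps fire regular-with-adaptation spike trains
    whose rate is rate_at_rheobase + f_i_slope · (I − rheobase).
    """
    p = cell_class_params
    if current_steps is None:
        current_steps = np.arange(-130.0, 251.0, 20.0)
    rng = substream(seed, "intrinsic")
    n_samples = int(round((pre_ms + step_ms + post_ms) / dt_ms)) + 1
    onset = int(round(pre_ms / dt_ms))
    offset = int(round((pre_ms + step_ms) / dt_ms))
    t_step = np.arange(n_samples - onset) * dt_ms

    sweeps = []
    for current in current_steps:
        v = np.full(n_samples, p.v_rest)
        dv_ss = current * p.input_resistance * 1e-3  # pA × MΩ → mV
        charge = dv_ss * (1.0 - np.exp(-t_step / p.tau))
        if current < 0 and p.sag > 0:
            # peak = ss / (1 − sag); the sag excess is a unit-peak difference
            # of exponentials scaled so the realized extreme hits dv_peak
            tau_sag = 150.0
            dv_peak = dv_ss / (1.0 - p.sag)
            t_h = p.tau * tau_sag / (tau_sag - p.tau) * np.log(tau_sag / p.tau)
            h = np.exp(-t_step / tau_sag) - np.exp(-t_step / p.tau)
            h = h / (np.exp(-t_h / tau_sag) - np.exp(-t_h / p.tau))
            base = dv_ss * (1.0 - np.exp(-t_step / p.tau))
            # scale the sag excess so the realized extreme hits dv_peak exactly
            alpha = dv_peak - dv_ss
            for _ in range(6):
                i_star = int(np.argmin(base + alpha * h))
                alpha = (dv_peak - base[i_star]) / h[i_star]
            charge = base + alpha * h
        v[onset:] += charge
        # return toward rest after the step
        t_post = np.arange(n_samples - offset) * dt_ms
        v[offset:] = p.v_rest + (v[offset - 1] - p.v_rest) * np.exp(-t_post / p.tau)

        if current >= p.rheobase:
            rate = p.rate_at_rheobase + p.f_i_slope * (current - p.rheobase)
            if rate > 0:
                mean_isi = 1000.0 / rate
                r = (1.0 + p.adaptation) / (1.0 - p.adaptation)
                n_max = int(np.ceil(rate * step_ms / 1000.0))
                # geometric ISI progression scaled to keep the mean rate
                raw = np.array([r**k for k in range(max(n_max, 1))])
                isis = raw / raw.mean() * mean_isi if raw.size else raw
                t_spk = pre_ms + 2.0 + np.cumsum(np.concatenate([[0.0], isis[:-1]]))
                for t in t_spk:
                    if t < pre_ms + step_ms:
                        _insert_ap(v, int(round(t / dt_ms)), dt_ms, p)
        if noise_sd > 0:
            v += ou_noise(rng, n_samples, dt_ms, noise_sd, 5.0)
        sweeps.append(
            (
                float(current),
                TraceEpoch(
                    sample_interval=dt_ms / 1000.0,
                    voltage=v,
                    stim_onset_index=onset,
                    stim_duration=step_ms,
                    holding_target=p.v_rest,
                ),
            )
        )
    return sweeps


# --------------------------------------------------------------------------
# whole experiments


@dataclass
class ExperimentConfig:
    """Configuration of one synthetic mapping experiment."""

    experiment_id: str = "sim-0"
    cre_line: str = "Rorb"
    expression_method: str = "AAV"
    stim_power_mw: float = 85.0
    n_patched: int = 3
    n_stim_cells: int = 60
    bounds: tuple[tuple[float, float], ...] = (
        (0.0, 300.0),
        (80.0, 600.0),
        (0.0, 100.0),
    )
    density_per_mm3: float = 12000.0
    base_connection_prob: float = 0.3
    connection_length_scale: float = 150.0  # µm, exponential falloff
    synapse: QuantalSynapseParams = field(default_factory=QuantalSynapseParams)
    spiking: SpikingModel = field(default_factory=SpikingModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_sweeps: int = 10
    holding_target: float = -70.0
    polarity: int = 1  # +1 excitatory, −1 inhibitory
    opsin_positive_fraction_patched: float = 0.0
    generate_traces: bool = True
    amplitude_spread: float = 0.5  # log-normal sigma on per-pair quantal size

    def kernel(self, d: np.ndarray) -> np.ndarray:
        return self.base_connection_prob * np.exp(-d / self.connection_length_scale)

    def validate(self) -> None:
        if self.n_patched < 0 or self.n_stim_cells < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0.0 <= self.base_connection_prob <= 1.0:
            raise ValueError("base_connection_prob must be in [0, 1]")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class ExperimentTruth:
    """Ground truth attached to a generated experiment."""

    adjacency: np.ndarray  # (n_stim, n_patched) bool
    stim_positions: np.ndarray
    patched_positions: np.ndarray
    pair_truth: list[PhotoresponseTruth | None]


def gen_experiment(
    config: ExperimentConfig, seed: int
) -> tuple[ConnectivityDataset, ExperimentTruth]:
    """Compose a full synthetic mapping experiment with ground truth.

    Photostimulated candidates are drawn from a Poisson cell map
    (subsampled to ``n_stim_cells``), patched cells are placed in L2/3,
    the ground-truth network is drawn from the distance kernel, and —
    when ``generate_traces`` — every probed pair gets photo-evoked or
    noise-only sweeps.
    """
    config.validate()
    rng = substream(seed, "experiment", config.experiment_id)
    cell_map = gen_cell_map(config.density_per_mm3, config.bounds, seed)

    (x0, x1), (y0, y1), (z0, z1) = config.bounds
    n_patched = config.n_patched
    patched = np.column_stack(
        [
            rng.uniform(x0 + 50, x1 - 50, n_patched) if n_patched else np.empty(0),
            rng.uniform(max(y0, 120.0), min(y1, 300.0), n_patched)
            if n_patched
            else np.empty(0),
            rng.uniform(z0 + 20, z1 - 20, n_patched) if n_patched else np.empty(0),
        ]
    ).reshape(-1, 3)

    if cell_map.n_cells > config.n_stim_cells:
        keep = rng.choice(cell_map.n_cells, size=config.n_stim_cells, replace=False)
        stim_positions = cell_map.positions[np.sort(keep)]
    else:
        stim_positions = cell_map.positions
    adjacency = gen_network(
        CellMapVolume(stim_positions, config.bounds), patched, config.kernel, seed
    )

    experiment = ExperimentRecord(
        experiment_id=config.experiment_id,
        cre_line=config.cre_line,
        expression_method=config.expression_method,
        stim_power_mw=config.stim_power_mw,
    )
    opsin_positive_posts = (
        rng.random(n_patched) < config.opsin_positive_fraction_patched
    )

    pairs: list[ProbedConnection] = []
    pair_exp: list[str] = []
    pair_truth: list[PhotoresponseTruth | None] = []
    for j in range(n_patched):
        post = CellRecord(
            cell_id=f"{config.experiment_id}-post{j}",
            role="patched",
            subclass_label="L2/3 PC",
            position=tuple(patched[j]),
            pia_distance=float(patched[j, 1]),
            opsin_positive=bool(opsin_positive_posts[j]),
        )
        for i in range(stim_positions.shape[0]):
            offset = stim_positions[i] - patched[j]
            geometry = PairGeometry(
                horizontal_offset=float(offset[0]),
                vertical_offset=float(offset[1]),
                presyn_pia_distance=float(stim_positions[i, 1]),
                distance_3d=float(np.linalg.norm(offset)),
            )
            pre = CellRecord(
                cell_id=f"{config.experiment_id}-stim{i}",
                role="photostimulated",
                subclass_label=config.cre_line,
                position=tuple(stim_positions[i]),
                pia_distance=float(stim_positions[i, 1]),
                opsin_positive=True,
            )
            connected = bool(adjacency[i, j])
            epochs: list[TraceEpoch] = []
            truth = None
            if config.generate_traces:
                synapse = None
                if connected:
                    scale = rng.lognormal(0.0, config.amplitude_spread)
                    synapse = replace(
                        config.synapse,
                        quantal_size=config.synapse.quantal_size * scale,
                    )
                epochs, truth = gen_photoresponse(
                    synapse,
                    config.spiking,
                    config.noise,
                    config.n_sweeps,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    holding_target=config.holding_target,
                    opsin_positive_post=bool(opsin_positive_posts[j]),
                    polarity=config.polarity,
                )
            pairs.append(
                ProbedConnection(
                    pre=pre,
                    post=post,
                    geometry=geometry,
                    epochs=epochs,
                    connected=CONNECTED if connected else NOT_CONNECTED,
                    annotation_source="ground_truth",
                )
            )
            pair_exp.append(config.experiment_id)
            pair_truth.append(truth)

    dataset = ConnectivityDataset(
        experiments=[experiment], pairs=pairs, pair_experiment=pair_exp
    )
    truth_bundle = ExperimentTruth(
        adjacency=adjacency,
        stim_positions=stim_positions,
        patched_positions=patched,
        pair_truth=pair_truth,
    )
    return dataset, truth_bundle
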