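"""Core domain types, coordinate conventions, layer assignment, and table I/O.

Units follow the conventions used throughout the package: distances in µm,
voltages in mV, times in ms unless a field states otherwise (the sweep
sample interval is in seconds). The stage frame is right-handed with the
optical axis as z; the slice rotation is applied about the optical axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

# Connection-state labels for a probed (photostimulated, patched) pair.
CONNECTED = "connected"
NOT_CONNECTED = "not_connected"
EXCLUDED_ARTIFACT = "excluded_artifact"

#: Representative cortical layer boundaries, µm from the pial surface.
#: Bins are half-open [lo, hi): a cell exactly at 330 µm is in L4.
LAYER_BOUNDARIES: tuple[tuple[str, float, float], ...] = (
    ("L1", 0.0, 80.0),
    ("L2/3", 80.0, 330.0),
    ("L4", 330.0, 480.0),
    ("L5", 480.0, 750.0),
    ("L6", 750.0, 1000.0),
)

#: Sentinel layer label for cells deeper than the last boundary.
BELOW_L6 = "below L6"


@dataclass(frozen=True)
class LayerBoundaries:
    """Ordered layer boundaries in µm from the pia."""

    boundaries: tuple[tuple[str, float, float], ...] = LAYER_BOUNDARIES

    def __post_init__(self) -> None:
        edges = [lo for _, lo, _ in self.boundaries] + [self.boundaries[-1][2]]
        if not all(a < b for a, b in zip(edges, edges[1:])):
            raise ValueError("layer boundaries must be strictly increasing")


@dataclass
class TraceEpoch:
    """One stimulus-aligned current-clamp voltage sweep.

    Parameters
    ----------
    sample_interval:
        Sampling interval in seconds (e.g. 2e-5 for 50 kHz).
    voltage:
        Membrane potential samples in mV.
    stim_onset_index:
        Sample index of photostimulus onset.
    stim_duration:
        Photostimulus duration in ms.
    holding_target:
        Target holding potential in mV (−70 for excitatory mapping,
        −55 for inhibitory mapping).
    sweep_index:
        Ordinal of this sweep within repeated stimulation of one target.
    """

    sample_interval: float
    voltage: np.ndarray
    stim_onset_index: int
    stim_duration: float = 10.0
    holding_target: float = -70.0
    sweep_index: int = 0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not 0 <= self.stim_onset_index < self.voltage.size:
            raise ValueError("stim_onset_index outside trace")
        if self.pre_stim_ms < 70.0 - 1e-9:
            raise ValueError("need at least 70 ms of pre-stimulus samples")
        if self.post_stim_ms < 50.0 - 1e-9:
            raise ValueError("need at least 50 ms of post-stimulus samples")

    @property
    def dt_ms(self) -> float:
        return self.sample_interval * 1000.0

    @property
    def pre_stim_ms(self) -> float:
        return self.stim_onset_index * self.dt_ms

    @property
    def post_stim_ms(self) -> float:
        return (self.voltage.size - self.stim_onset_index - 1) * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset."""
        return (np.arange(self.voltage.size) - self.stim_onset_index) * self.dt_ms

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Sample slice for a [start, stop) ms window relative to onset."""
        i0 = self.stim_onset_index + int(round(start_ms / self.dt_ms))
        i1 = self.stim_onset_index + int(round(stop_ms / self.dt_ms))
        return slice(max(i0, 0), min(i1, self.voltage.size))


@dataclass
class CellRecord:
    """An identified cell: photostimulated candidate, patched target, or both."""

    cell_id: str
    role: str  # "photostimulated" | "patched" | "both"
    subclass_label: str
    position: tuple[float, float, float]  # (x, y, z) µm, stage frame
    pia_distance: float = float("nan")
    depth_below_surface: float = float("nan")
    opsin_positive: bool = False

    def __post_init__(self) -> None:
        if not math.isnan(self.pia_distance) and self.pia_distance < 0:
            raise ValueError("pia_distance must be >= 0")
        if not math.isnan(self.depth_below_surface) and self.depth_below_surface < 0:
            raise ValueError("depth_below_surface must be >= 0")


@dataclass
class PairGeometry:
    """Relative geometry of one probed (pre, post) pair.

    ``horizontal_offset`` is signed (positive = presynaptic cell posterior);
    ``vertical_offset`` runs along the pia→white-matter axis;
    ``distance_3d`` is the Euclidean distance in three dimensions.
    """

    horizontal_offset: float
    vertical_offset: float
    presyn_pia_distance: float
    distance_3d: float

    def __post_init__(self) -> None:
        if self.distance_3d < 0:
            raise ValueError("distance_3d must be >= 0")
        if self.distance_3d + 1e-6 < abs(self.horizontal_offset):
            raise ValueError("distance_3d cannot be smaller than |horizontal_offset|")


@dataclass
class ProbedConnection:
    """One (photostimulated cell, patched cell) pair and everything measured on it."""

    pre: CellRecord
    post: CellRecord
    geometry: PairGeometry
    epochs: list[TraceEpoch] = field(default_factory=list)
    connected: str = NOT_CONNECTED
    annotation_source: str = "ground_truth"
    psp_metrics: "object | None" = None

    def __post_init__(self) -> None:
        if self.connected not in (CONNECTED, NOT_CONNECTED, EXCLUDED_ARTIFACT):
            raise ValueError(f"invalid connection state {self.connected!r}")


@dataclass
class ExperimentRecord:
    """Metadata for one mapping experiment (one Cre line / expression method)."""

    experiment_id: str
    cre_line: str
    expression_method: str  # "AAV" | "Ai167"
    stim_power_mw: float = 85.0


@dataclass
class ConnectivityDataset:
    """All probed connections across experiments; substrate of the statistics."""

    experiments: list[ExperimentRecord] = field(default_factory=list)
    pairs: list[ProbedConnection] = field(default_factory=list)
    pair_experiment: list[str] = field(default_factory=list)  # experiment_id per pair
    extras: pd.DataFrame | None = None  # opaque extra columns from tolerant reads

    def __post_init__(self) -> None:
        if self.pair_experiment and len(self.pair_experiment) != len(self.pairs):
            raise ValueError("pair_experiment must align with pairs")
        known = {e.experiment_id for e in self.experiments}
        if self.pair_experiment and not set(self.pair_experiment) <= known:
            raise ValueError("pair references unknown experiment")

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the connection-table schema (one row per probed pair)."""
        exp_by_id = {e.experiment_id: e for e in self.experiments}
        rows = []
        for pair, exp_id in zip(self.pairs, self.pair_experiment):
            exp = exp_by_id[exp_id]
            m = pair.psp_metrics
            rows.append(
                {
                    "experiment_id": exp_id,
                    "cre_line": exp.cre_line,
                    "expression_method": exp.expression_method,
                    "stim_power_mw": exp.stim_power_mw,
                    "pre_cell_id": pair.pre.cell_id,
                    "post_cell_id": pair.post.cell_id,
                    "post_subclass": pair.post.subclass_label,
                    "pre_pia_um": pair.geometry.presyn_pia_distance,
                    "post_pia_um": pair.post.pia_distance,
                    "horizontal_offset_um": pair.geometry.horizontal_offset,
                    "distance_3d_um": pair.geometry.distance_3d,
                    "connected": pair.connected == CONNECTED,
                    "artifact_excluded": pair.connected == EXCLUDED_ARTIFACT,
                    "n_sweeps": len(pair.epochs),
                    "psp_amplitude_mv": getattr(m, "amplitude", np.nan),
                    "psp_cv": getattr(m, "cv", np.nan),
                    "rise_time_ms": getattr(m, "rise_20_80", np.nan),
                    "latency_ms": getattr(m, "onset_time", np.nan),
                    "ppr": getattr(m, "ppr", np.nan),
                }
            )
        frame = pd.DataFrame(rows, columns=CONNECTION_TABLE_COLUMNS)
        if self.extras is not None and len(self.extras) == len(frame):
            frame = pd.concat([frame, self.extras.reset_index(drop=True)], axis=1)
        return frame


CONNECTION_TABLE_COLUMNS = [
    "experiment_id",
    "cre_line",
    "expression_method",
    "stim_power_mw",
    "pre_cell_id",
    "post_cell_id",
    "post_subclass",
    "pre_pia_um",
    "post_pia_um",
    "horizontal_offset_um",
    "distance_3d_um",
    "connected",
    "artifact_excluded",
    "n_sweeps",
    "psp_amplitude_mv",
    "psp_cv",
    "rise_time_ms",
    "latency_ms",
    "ppr",
]


def assign_layer(pia_distance: float) -> str:
    """Map a pia distance (µm) to a cortical layer label.

    Uses half-open bins [lo, hi); distances beyond the last boundary return
    the ``below L6`` sentinel.
    """
    if pia_distance < 0 or math.isnan(pia_distance):
        raise ValueError("pia_distance must be >= 0")
    for label, lo, hi in LAYER_BOUNDARIES:
        if lo <= pia_distance < hi:
            return label
    return BELOW_L6


def transform_coordinates(
    stage_positions: Sequence[tuple[float, float, float]],
    slice_rotation: float,
    reference_patched_cell: CellRecord,
) -> list[PairGeometry]:
    """Convert stage-frame presynaptic positions to slice-aligned pair geometry.

    The in-plane (x, y) offset from the patched cell is rotated about the
    optical axis by ``slice_rotation`` (degrees, counter-clockwise) so that
    the first rotated axis is the horizontal (anterior→posterior) direction
    and the second runs along the pia→white-matter axis. Vertical offsets
    added to the reference cell's measured pia distance give the presynaptic
    pia distances. The 3D distance is the Euclidean norm of the full offset,
    which is invariant under the in-plane rotation.
    """
    if slice_rotation is None or (
        isinstance(slice_rotation, float) and math.isnan(slice_rotation)
    ):
        raise ValueError("missing slice rotation angle")
    if math.isnan(reference_patched_cell.pia_distance):
        raise ValueError("reference patched cell has no measured pia distance")

    theta = math.radians(slice_rotation)
    c, s = math.cos(theta), math.sin(theta)
    ref = np.asarray(reference_patched_cell.position, dtype=float)
    out = []
    for pos in stage_positions:
        d = np.asarray(pos, dtype=float) - ref
        horiz = c * d[0] - s * d[1]
        vert = s * d[0] + c * d[1]
        out.append(
            PairGeometry(
                horizontal_offset=horiz,
                vertical_offset=vert,
                presyn_pia_distance=reference_patched_cell.pia_distance + vert,
                distance_3d=float(np.linalg.norm(d)),
            )
        )
    return out


def write_connection_table(dataset: ConnectivityDataset | pd.DataFrame, path) -> None:
    """Write a connection table as CSV (floats at 6 significant digits)."""
    frame = dataset if isinstance(dataset, pd.DataFrame) else dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.6g")


def read_connection_table(path) -> ConnectivityDataset:
    """Read a connection-table CSV into a :class:`ConnectivityDataset`.

    The reader is tolerant: unknown extra columns are preserved as opaque
    metadata on ``dataset.extras``. A missing mandatory column raises with
    the column named.
    """
    frame = pd.read_csv(path)
    missing = [c for c in CONNECTION_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"connection table missing mandatory column(s): {missing}")
    extras_cols = [c for c in frame.columns if c not in CONNECTION_TABLE_COLUMNS]

    experiments: dict[str, ExperimentRecord] = {}
    pairs: list[ProbedConnection] = []
    pair_experiment: list[str] = []
    for row in frame.itertuples(index=False):
        exp_id = str(row.experiment_id)
        experiments.setdefault(
            exp_id,
            ExperimentRecord(
                experiment_id=exp_id,
                cre_line=str(row.cre_line),
                expression_method=str(row.expression_method),
                stim_power_mw=float(row.stim_power_mw),
            ),
        )
        geometry = PairGeometry(
            horizontal_offset=float(row.horizontal_offset_um),
            vertical_offset=float(row.pre_pia_um) - float(row.post_pia_um),
            presyn_pia_distance=float(row.pre_pia_um),
            distance_3d=float(row.distance_3d_um),
        )
        if bool(row.artifact_excluded):
            state = EXCLUDED_ARTIFACT
        elif bool(row.connected):
            state = CONNECTED
        else:
            state = NOT_CONNECTED
        from .psp import PspMetrics  # local import to avoid a cycle

        metrics = None
        if np.isfinite(row.psp_amplitude_mv):
            metrics = PspMetrics(
                amplitude=float(row.psp_amplitude_mv),
                cv=float(row.psp_cv),
                rise_20_80=float(row.rise_time_ms),
                onset_time=float(row.latency_ms),
                n_accepted_sweeps=int(row.n_sweeps),
                ppr=float(row.ppr),
            )
        pairs.append(
            ProbedConnection(
                pre=CellRecord(
                    cell_id=str(row.pre_cell_id),
                    role="photostimulated",
                    subclass_label=str(row.cre_line),
                    position=(float(row.horizontal_offset_um), float(row.pre_pia_um), 0.0),
                    pia_distance=float(row.pre_pia_um),
                    opsin_positive=True,
                ),
                post=CellRecord(
                    cell_id=str(row.post_cell_id),
                    role="patched",
                    subclass_label=str(row.post_subclass),
                    position=(0.0, float(row.post_pia_um), 0.0),
                    pia_distance=float(row.post_pia_um),
                ),
                geometry=geometry,
                epochs=[],
                connected=state,
                psp_metrics=metrics,
            )
        )
        pair_experiment.append(exp_id)

    extras = frame[extras_cols].copy() if extras_cols else None
    return ConnectivityDataset(
        experiments=list(experiments.values()),
        pairs=pairs,
        pair_experiment=pair_experiment,
        extras=extras,
    )


def write_sweeps(path, sweep_groups: dict[str, Iterable[TraceEpoch]]) -> None:
    """Write sweeps to an HDF5 container: one group per probed pair.

    Each group stores a (n_sweeps, n_samples) ``voltage`` dataset plus the
    :class:`TraceEpoch` timing metadata as attributes.
    """
    with h5py.File(path, "w") as handle:
        for key, epochs in sweep_groups.items():
            epochs = list(epochs)
            if not epochs:
                continue
            grp = handle.create_group(key)
            grp.create_dataset(
                "voltage", data=np.stack([e.voltage for e in epochs])
            )
            first = epochs[0]
            grp.attrs["sample_interval"] = first.sample_interval
            grp.attrs["stim_onset_index"] = first.stim_onset_index
            grp.attrs["stim_duration"] = first.stim_duration
            grp.attrs["holding_target"] = first.holding_target


def read_sweeps(path) -> dict[str, list[TraceEpoch]]:
    """Read an HDF5 sweep container written by :func:`write_sweeps`."""
    out: dict[str, list[TraceEpoch]] = {}
    with h5py.File(path, "r") as handle:
        for key in handle:
            grp = handle[key]
            volts = np.asarray(grp["voltage"])
            out[key] = [
                TraceEpoch(
                    sample_interval=float(grp.attrs["sample_interval"]),
                    voltage=v,
                    stim_onset_index=int(grp.attrs["stim_onset_index"]),
                    stim_duration=float(grp.attrs["stim_duration"]),
                    holding_target=float(grp.attrs["holding_target"]),
                    sweep_index=i,
                )
                for i, v in enumerate(volts)
            ]
    return out
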