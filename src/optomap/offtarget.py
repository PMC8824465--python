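"""Off-target activation modelling from labeled-cell maps and stimulus resolution.

The question: when a photostimulus is aimed at one opsin-expressing cell,
how many of its labeled neighbors fire too? The estimate combines

1. an edge-corrected 2D histogram of neighbors per targeted cell over
   (lateral, axial) offset bins,
2. an activation-probability map built from the per-axis Gaussian
   resolution fits under the *min rule* — a neighbor at combined offsets
   is assigned the lower of the two probabilities predicted by the
   independent lateral and axial offsets,
3. their elementwise product summed over all bins (expected off-target
   cells per stimulus),

plus an analytic variant for a homogeneous cell density and the
response-probability identity P_response = 1 − (1 − P_connection)^n used
to reason about how off-target activation distorts measured connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .resolution import ResolutionProfile


@dataclass
class CellMapVolume:
    """A bounded 3D volume (µm) with annotated labeled-cell positions.

    ``bounds`` is ((x0, x1), (y0, y1), (z0, z1)); by package convention
    the y axis runs along pia→white matter, and the z axis is the optical
    (axial) axis.
    """

    positions: np.ndarray  # (n, 3) µm
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        for lo, hi in self.bounds:
            if not hi > lo:
                raise ValueError("degenerate volume bounds")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def volume_um3(self) -> float:
        return float(np.prod([hi - lo for lo, hi in self.bounds]))


@dataclass
class NeighborHistogram:
    """Mean neighbors per targeted cell over (lateral, axial) offset bins.

    ``values[i, j]`` is the edge-corrected mean number of neighbors with
    lateral (x, z-plane radial) offset in ``lateral_edges[i:i+2]`` and
    axial offset |Δz| in ``axial_edges[j:j+2]``. Entries with zero
    eligible seed cells are NaN.
    """

    values: np.ndarray
    lateral_edges: np.ndarray
    axial_edges: np.ndarray
    eligible_seeds: np.ndarray = field(default=None)  # per-bin seed counts


@dataclass
class ActivationProbMap:
    """Off-target activation probability over the same offset bins."""

    values: np.ndarray
    lateral_edges: np.ndarray
    axial_edges: np.ndarray


@dataclass
class ResponseProbabilityModel:
    """Eq.-style response model: P_response = 1 − (1 − P_connection)^n."""

    p_connection: float
    n_activated: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_connection <= 1.0:
            raise ValueError("p_connection must be in [0, 1]")
        if self.n_activated < 1:
            raise ValueError("n_activated must be >= 1")

    @property
    def p_response(self) -> float:
        return p_response(self.p_connection, self.n_activated)


def labeled_density(cell_map: CellMapVolume) -> float:
    """Labeled-cell density in cells/mm³ (count ÷ imaged volume)."""
    vol = cell_map.volume_um3
    if vol <= 0:
        raise ValueError("zero volume")
    return cell_map.n_cells / vol * 1e9


def density_from_reference_image(
    n_cells: int, area_um2: float, thickness_um: float
) -> float:
    """Density variant for 2D reference images: count ÷ (area × thickness)."""
    vol = area_um2 * thickness_um
    if vol <= 0:
        raise ValueError("zero volume")
    return n_cells / vol * 1e9


def neighbor_histogram(
    cell_map: CellMapVolume,
    lateral_bin: float = 10.0,
    axial_bin: float = 10.0,
    max_lateral: float = 100.0,
    max_axial: float = 100.0,
) -> NeighborHistogram:
    """Edge-corrected neighbors per targeted cell at combined offsets.

    Lateral offset is the radial distance in the plane normal to the
    optical axis; axial offset is |Δz|. Each bin's pair count is divided
    by the number of seed cells far enough from every volume face that
    the full annulus × (symmetric axial slab) of that bin lies inside the
    imaged volume — so unimaged neighbors outside the volume do not bias
    the per-cell mean. The targeted cell is excluded from its own counts.
    """
    if cell_map.n_cells == 0:
        raise ValueError("need at least one cell")
    pos = cell_map.positions
    lat_edges = np.arange(0.0, max_lateral + lateral_bin / 2, lateral_bin)
    ax_edges = np.arange(0.0, max_axial + axial_bin / 2, axial_bin)
    (x0, x1), (y0, y1), (z0, z1) = cell_map.bounds

    diff = pos[:, None, :] - pos[None, :, :]
    lat = np.hypot(diff[..., 0], diff[..., 1])
    ax = np.abs(diff[..., 2])
    np.fill_diagonal(lat, np.inf)  # self-exclusion

    counts = np.zeros((lat_edges.size - 1, ax_edges.size - 1))
    eligible = np.zeros_like(counts)
    for i in range(lat_edges.size - 1):
        r_out = lat_edges[i + 1]
        ok_lat = (
            (pos[:, 0] - r_out >= x0)
            & (pos[:, 0] + r_out <= x1)
            & (pos[:, 1] - r_out >= y0)
            & (pos[:, 1] + r_out <= y1)
        )
        for j in range(ax_edges.size - 1):
            a_out = ax_edges[j + 1]
            ok = ok_lat & (pos[:, 2] - a_out >= z0) & (pos[:, 2] + a_out <= z1)
            eligible[i, j] = ok.sum()
            if not ok.any():
                continue
            in_bin = (
                (lat[ok] >= lat_edges[i])
                & (lat[ok] < r_out)
                & (ax[ok] >= ax_edges[j])
                & (ax[ok] < a_out)
            )
            counts[i, j] = in_bin.sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(eligible > 0, counts / np.maximum(eligible, 1), np.nan)
    return NeighborHistogram(
        values=values,
        lateral_edges=lat_edges,
        axial_edges=ax_edges,
        eligible_seeds=eligible,
    )


def min_rule_probability(
    profile: ResolutionProfile, lateral_um, axial_um
) -> np.ndarray:
    """Activation probability at combined offsets: the lower of the two
    probabilities predicted by the independent lateral and axial Gaussians."""
    return np.minimum(
        profile.lateral_probability(np.abs(lateral_um)),
        profile.axial_probability(np.abs(axial_um)),
    )


def activation_prob_map(
    profile: ResolutionProfile,
    lateral_edges: np.ndarray,
    axial_edges: np.ndarray,
    grid_um: float = 1.0,
) -> ActivationProbMap:
    """Bin-averaged min-rule probability map on the histogram's grid.

    The probability surface is evaluated on a ``grid_um`` lattice (1 µm by
    default) and averaged within each (lateral, axial) bin.
    """
    lateral_edges = np.asarray(lateral_edges, dtype=float)
    axial_edges = np.asarray(axial_edges, dtype=float)
    values = np.zeros((lateral_edges.size - 1, axial_edges.size - 1))
    for i in range(lateral_edges.size - 1):
        lat = np.arange(lateral_edges[i], lateral_edges[i + 1], grid_um) + grid_um / 2
        for j in range(axial_edges.size - 1):
            ax = np.arange(axial_edges[j], axial_edges[j + 1], grid_um) + grid_um / 2
            grid = min_rule_probability(profile, lat[:, None], ax[None, :])
            values[i, j] = float(np.mean(grid))
    return ActivationProbMap(
        values=values, lateral_edges=lateral_edges, axial_edges=axial_edges
    )


def expected_offtarget(hist: NeighborHistogram, prob_map: ActivationProbMap) -> float:
    """Expected off-target cells per stimulus: Σ bins (neighbors × probability).

    Undefined histogram bins (no eligible seeds) are skipped with a warning.
    """
    if not (
        np.array_equal(hist.lateral_edges, prob_map.lateral_edges)
        and np.array_equal(hist.axial_edges, prob_map.axial_edges)
    ):
        raise ValueError("histogram and probability map bin grids differ")
    undefined = ~np.isfinite(hist.values)
    if undefined.any():
        warnings.warn(
            f"skipping {int(undefined.sum())} histogram bin(s) with no eligible seeds",
            stacklevel=2,
        )
    vals = np.where(undefined, 0.0, hist.values)
    return float(np.sum(vals * prob_map.values))


def homogeneous_offtarget(
    density_per_mm3: float,
    fwhm_lateral: float,
    fwhm_axial: float,
    epsrel: float = 1e-6,
) -> float:
    """Expected off-target cells per stimulus for a homogeneous density.

    Integrates the min-rule activation probability over all space,
    ρ ∫∫ min(g_lat(r), g_ax(z)) 2πr dr dz, for unit-amplitude axis
    Gaussians with the given FWHMs. The targeted cell sits at the origin
    of the Poisson field and contributes nothing to the neighbor integral
    (a point has zero measure), so the result counts off-target cells only.
    The radial integral has a closed form at fixed z; only the axial
    integral is evaluated by adaptive quadrature.
    """
    if density_per_mm3 < 0:
        raise ValueError("density must be >= 0")
    if density_per_mm3 == 0:
        return 0.0
    profile = ResolutionProfile.from_fwhm(fwhm_lateral, fwhm_axial)
    sig_r = profile.sigma_lateral
    sig_z = profile.sigma_axial

    def radial_integral(z: float) -> float:
        # min(g_r(r), g_z) = g_z for r <= r*, g_r(r) beyond; both pieces closed form
        g_z = float(np.exp(-(z**2) / (2.0 * sig_z**2)))
        r_star_sq = -2.0 * sig_r**2 * np.log(g_z) if g_z < 1.0 else 0.0
        return float(np.pi * g_z * (r_star_sq + 2.0 * sig_r**2))

    axial, _ = integrate.quad(
        radial_integral, 0.0, 10.0 * sig_z, epsrel=epsrel, limit=200
    )
    volume_um3 = 2.0 * axial  # symmetric in z
    return density_per_mm3 * volume_um3 * 1e-9


def p_response(p_connection: float, n: float) -> float:
    """Probability of any response when n cells with connection probability
    p are activated: 1 − (1 − p)^n."""
    p = np.asarray(p_connection, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_connection must be in [0, 1]")
    if np.any(np.asarray(n) < 1):
        raise ValueError("n must be >= 1")
    return float(1.0 - (1.0 - p) ** n) if np.ndim(p) == 0 and np.ndim(n) == 0 else 1.0 - (1.0 - p) ** n
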