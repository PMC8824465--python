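"""Convergence/divergence motif counting and the bootstrap null model.

A convergence motif is two photostimulated cells both connected to one
patched cell; a divergence motif is one photostimulated cell connected to
two simultaneously recorded patched cells. Observed motif counts are
compared to a null that redraws every probed pair as an independent
Bernoulli at the connection probability estimated for its (horizontal
distance × presynaptic pia distance × subclass) bin — so the null keeps
the distance and subclass structure of the measured network, and excess
motifs indicate hub-like wiring beyond spatial proximity.

Completed-motif conditional probabilities (P_j|i: the probability that a
second candidate completes the motif given the first edge is present)
provide the complementary, assumption-free view of the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CONNECTED, EXCLUDED_ARTIFACT, ConnectivityDataset
from .stats import jeffreys_interval


@dataclass
class MotifCounts:
    """Observed motif counts and their eligible-pair denominators."""

    convergence: int  # connected (2 presyn → 1 postsyn) pairs
    convergence_eligible: int  # all probed presyn pairs sharing a post
    divergence: int  # connected (1 presyn → 2 postsyn) pairs
    divergence_eligible: int  # all probed post pairs sharing a presyn
    divergent_cells: int  # presyn cells connected to >= 2 recorded posts


@dataclass
class BootstrapNull:
    """Bootstrap null distribution of a motif count."""

    observed: int
    simulated: np.ndarray
    n_simulations: int

    @property
    def p_value(self) -> float:
        """One-sided exceedance fraction (0 means below the sentinel)."""
        return float(np.mean(self.simulated >= self.observed))

    @property
    def report(self) -> str:
        if self.p_value == 0.0:
            return f"<{1.0 / self.n_simulations:g}"
        return f"{self.p_value:g}"


def _pair_frame(dataset: ConnectivityDataset) -> pd.DataFrame:
    rows = []
    for pair, exp_id in zip(dataset.pairs, dataset.pair_experiment):
        rows.append(
            {
                "experiment": exp_id,
                "pre_id": pair.pre.cell_id,
                "post_id": pair.post.cell_id,
                "cre_line": pair.pre.subclass_label,
                "post_subclass": pair.post.subclass_label,
                "connected": pair.connected == CONNECTED,
                "artifact": pair.connected == EXCLUDED_ARTIFACT,
                "horizontal": pair.geometry.horizontal_offset,
                "pre_pia": pair.geometry.presyn_pia_distance,
                "pre_pos": pair.pre.position,
                "post_pos": pair.post.position,
                "amplitude": getattr(pair.psp_metrics, "amplitude", np.nan),
            }
        )
    frame = pd.DataFrame(rows)
    return frame[~frame["artifact"]].reset_index(drop=True) if not frame.empty else frame


def _choose2(k: np.ndarray) -> np.ndarray:
    return k * (k - 1) / 2.0


def count_motifs(dataset: ConnectivityDataset) -> MotifCounts:
    """Exhaustive motif enumeration (artifact-excluded pairs ignored)."""
    frame = _pair_frame(dataset)
    if frame.empty:
        return MotifCounts(0, 0, 0, 0, 0)
    post_groups = frame.groupby(["experiment", "post_id"])
    conv = int(sum(_choose2(np.array([g["connected"].sum()])).item() for _, g in post_groups))
    conv_elig = int(sum(_choose2(np.array([len(g)])).item() for _, g in post_groups))
    pre_groups = frame.groupby(["experiment", "pre_id"])
    div = int(sum(_choose2(np.array([g["connected"].sum()])).item() for _, g in pre_groups))
    div_elig = int(sum(_choose2(np.array([len(g)])).item() for _, g in pre_groups))
    div_cells = int(sum(1 for _, g in pre_groups if g["connected"].sum() >= 2))
    return MotifCounts(conv, conv_elig, div, div_elig, div_cells)


def _conditional_curve(
    distances: np.ndarray,
    completed: np.ndarray,
    bin_width: float,
) -> pd.DataFrame:
    if distances.size == 0:
        return pd.DataFrame(
            columns=["bin_lo", "bin_hi", "numerator", "denominator", "probability",
                     "jeffreys_lo", "jeffreys_hi"]
        )
    edges = np.arange(0.0, distances.max() + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (distances >= lo) & (distances < hi)
        denom = int(sel.sum())
        if denom == 0:
            continue
        num = int(completed[sel].sum())
        ci = jeffreys_interval(num, denom)
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "numerator": num,
                "denominator": denom,
                "probability": num / denom,
                "jeffreys_lo": ci[0],
                "jeffreys_hi": ci[1],
            }
        )
    return pd.DataFrame(rows)


def completed_convergence(
    dataset: ConnectivityDataset,
    distance_axis: str = "between_presyn",
    bin_width: float = 100.0,
) -> pd.DataFrame:
    """P_j|i per distance bin for convergence onto a shared patched cell.

    All ordered pairs (i, j) of photostimulated cells probed against the
    same patched cell, with cell i connected, form the denominator; the
    numerator counts pairs where cell j is also connected. ``distance_axis``
    is ``"between_presyn"`` (|horizontal| between the two photostimulated
    cells) or ``"presyn_to_post"`` (|horizontal| from cell j to the
    patched cell).
    """
    frame = _pair_frame(dataset)
    dists, completed = [], []
    for _, g in frame.groupby(["experiment", "post_id"]):
        h = g["horizontal"].to_numpy(float)
        conn = g["connected"].to_numpy(bool)
        n = len(g)
        for i in range(n):
            if not conn[i]:
                continue
            for j in range(n):
                if j == i:
                    continue
                if distance_axis == "between_presyn":
                    dists.append(abs(h[i] - h[j]))
                elif distance_axis == "presyn_to_post":
                    dists.append(abs(h[j]))
                else:
                    raise ValueError(f"unknown distance_axis {distance_axis!r}")
                completed.append(conn[j])
    return _conditional_curve(
        np.asarray(dists, float), np.asarray(completed, bool), bin_width
    )


def completed_divergence(
    dataset: ConnectivityDataset,
    bin_width: float = 100.0,
    restrict_j_subclass: str | None = None,
) -> pd.DataFrame:
    """P_j|i per distance bin for divergence onto recorded cell pairs.

    All ordered pairs (i, j) of patched cells probed against the same
    photostimulated cell, with cell i receiving a connection, form the
    denominator; the numerator counts pairs where cell j also receives
    one. Distance is the 3D intersomatic distance between the patched
    cells. ``restrict_j_subclass`` limits cell j (e.g. to "L2/3 PC") when
    comparing against an overall connection probability.
    """
    frame = _pair_frame(dataset)
    dists, completed = [], []
    for _, g in frame.groupby(["experiment", "pre_id"]):
        conn = g["connected"].to_numpy(bool)
        pos = np.array([p for p in g["post_pos"]], dtype=float)
        subclass = g["post_subclass"].to_numpy()
        n = len(g)
        for i in range(n):
            if not conn[i]:
                continue
            for j in range(n):
                if j == i:
                    continue
                if restrict_j_subclass and subclass[j] != restrict_j_subclass:
                    continue
                dists.append(float(np.linalg.norm(pos[i] - pos[j])))
                completed.append(conn[j])
    return _conditional_curve(
        np.asarray(dists, float), np.asarray(completed, bool), bin_width
    )


def connection_probability_table(
    frame: pd.DataFrame,
    bin_um: float = 100.0,
    laplace_smoothing: bool = False,
) -> np.ndarray:
    """Per-pair connection probability from (horizontal × pia × subclass) bins.

    100 µm × 100 µm bins of |horizontal offset| × presynaptic pia distance,
    stratified by (Cre line, postsynaptic subclass). Bins with zero found
    connections contribute probability 0 unless ``laplace_smoothing`` adds
    one pseudo-success and one pseudo-failure per bin.
    """
    h_bin = np.floor(np.abs(frame["horizontal"].to_numpy(float)) / bin_um).astype(int)
    p_bin = np.floor(frame["pre_pia"].to_numpy(float) / bin_um).astype(int)
    keys = pd.DataFrame(
        {
            "h": h_bin,
            "p": p_bin,
            "cre": frame["cre_line"].to_numpy(),
            "sub": frame["post_subclass"].to_numpy(),
        }
    )
    grouped = keys.assign(conn=frame["connected"].to_numpy(bool)).groupby(
        ["h", "p", "cre", "sub"]
    )["conn"]
    found = grouped.transform("sum").to_numpy(float)
    probed = grouped.transform("count").to_numpy(float)
    if laplace_smoothing:
        return (found + 1.0) / (probed + 2.0)
    return found / probed


def bootstrap_motif_test(
    dataset: ConnectivityDataset,
    n_simulations: int = 1000,
    seed: int = 0,
    bin_um: float = 100.0,
    laplace_smoothing: bool = False,
    probability_table: np.ndarray | None = None,
) -> dict[str, BootstrapNull]:
    """Bootstrap null for convergence and divergence motif counts.

    The connection probability of every probed pair is estimated from its
    (|horizontal| × presynaptic-pia × subclass) bin in this same dataset;
    each simulation independently redraws every pair's Bernoulli outcome
    at that probability (geometry and subclasses fixed) and re-counts
    motifs. p-values are one-sided exceedance fractions; an observed count
    above every simulation reports the "<1/n_simulations" sentinel.

    Because the default table is estimated from the same dataset it is
    tested against, null p-values concentrate mildly toward 0.5 (the
    plug-in fit pins the simulated edge total to the observed one), which
    makes the test conservative for detecting motif excess. Supplying a
    per-pair ``probability_table`` from an independent source (or the
    known generating model, in calibration studies) restores exact
    exceedance calibration.
    """
    frame = _pair_frame(dataset)
    observed = count_motifs(dataset)
    if frame.empty:
        raise ValueError("empty dataset")
    if probability_table is not None:
        p_vec = np.asarray(probability_table, dtype=float)
        if p_vec.shape != (len(frame),) or np.any((p_vec < 0) | (p_vec > 1)):
            raise ValueError("probability_table must give one probability per pair")
    else:
        p_vec = connection_probability_table(frame, bin_um, laplace_smoothing)

    post_codes = pd.factorize(
        frame["experiment"].astype(str) + "//" + frame["post_id"].astype(str)
    )[0]
    pre_codes = pd.factorize(
        frame["experiment"].astype(str) + "//" + frame["pre_id"].astype(str)
    )[0]
    n_posts = post_codes.max() + 1
    n_pres = pre_codes.max() + 1

    rng = np.random.default_rng(seed)
    conv_sim = np.empty(n_simulations)
    div_sim = np.empty(n_simulations)
    for s in range(n_simulations):
        conn = rng.random(p_vec.size) < p_vec
        k_post = np.bincount(post_codes, weights=conn, minlength=n_posts)
        k_pre = np.bincount(pre_codes, weights=conn, minlength=n_pres)
        conv_sim[s] = _choose2(k_post).sum()
        div_sim[s] = _choose2(k_pre).sum()

    return {
        "convergence": BootstrapNull(observed.convergence, conv_sim, n_simulations),
        "divergence": BootstrapNull(observed.divergence, div_sim, n_simulations),
    }


def amplitude_correlation(
    amplitude_pairs: np.ndarray, log_space: bool = False
) -> tuple[float, float]:
    """Pearson r of connection strengths sharing a pre- or postsynaptic cell.

    Each unordered amplitude pair is double-plotted — entered once as
    (i, j) and once as (j, i) — so the assignment of which connection is
    "first" cannot bias r; significance uses the number of *unique*
    unordered pairs as the sample size.
    """
    pairs = np.asarray(amplitude_pairs, dtype=float).reshape(-1, 2)
    n_unique = pairs.shape[0]
    if n_unique < 3:
        raise ValueError("need >= 3 unique unordered pairs")
    if log_space:
        pairs = np.log(pairs)
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n_unique - 2
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    from scipy import stats as scistats

    p = float(2.0 * scistats.t.sf(abs(t), df))
    return r, p
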