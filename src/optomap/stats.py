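"""Connection-probability statistics and contingency testing.

Estimation of connection probability in distance bins with 95% Jeffreys
(Beta(½,½) equal-tailed) intervals, two-sided Fisher exact and Pearson
chi-squared contingency tests, Benjamini–Hochberg FDR adjustment, Cohen's
d effect sizes, rank-based group comparisons (Kruskal–Wallis with Dunn's
post hoc), and the cross-method comparison of optogenetic versus
paired-recording connection rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as scistats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


@dataclass
class BinnedProbability:
    """Connection probability in one distance bin with a Jeffreys interval."""

    bin_lo: float
    bin_hi: float
    found: int
    probed: int
    probability: float
    jeffreys_lo: float
    jeffreys_hi: float
    drawn: bool  # False when probed < the minimum-probed drawing rule


@dataclass
class MethodComparison:
    """Cross-method comparison over connection-class × distance categories."""

    table: pd.DataFrame  # per-category counts, probabilities, fisher_p, bh_p
    pearson_r: float
    pearson_p: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float


def jeffreys_interval(
    found: int, probed: int, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed Beta(found+½, probed−found+½) interval.

    Boundary convention: the lower bound is 0 when found = 0 and the
    upper bound is 1 when found = probed.
    """
    if not (0 <= found <= probed) or probed < 1:
        raise ValueError("need 0 <= found <= probed, probed >= 1")
    lo, hi = proportion_confint(found, probed, alpha=1 - level, method="jeffreys")
    if found == 0:
        lo = 0.0
    if found == probed:
        hi = 1.0
    return float(lo), float(hi)


def binned_connection_probability(
    pairs: pd.DataFrame,
    axis: str = "pia",
    bin_width: float = 100.0,
    min_probed: int = 20,
    max_distance: float = 1000.0,
) -> list[BinnedProbability]:
    """Per-bin connection probability along a distance axis.

    ``axis`` is one of ``"pia"`` (presynaptic pia distance),
    ``"horizontal"`` (|horizontal offset|), or ``"3d"`` (Euclidean
    distance). Artifact-excluded pairs never enter denominators; bins with
    fewer than ``min_probed`` probed pairs carry ``drawn=False`` (a
    figure-drawing rule only — the counts are still reported).
    """
    column = {
        "pia": "pre_pia_um",
        "horizontal": "horizontal_offset_um",
        "3d": "distance_3d_um",
    }[axis]
    if pairs.empty:
        return []
    keep = ~pairs["artifact_excluded"].astype(bool)
    values = pairs.loc[keep, column].astype(float).abs()
    connected = pairs.loc[keep, "connected"].astype(bool)

    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (values >= lo) & (values < hi)
        probed = int(in_bin.sum())
        if probed == 0:
            continue
        found = int(connected[in_bin].sum())
        ci = jeffreys_interval(found, probed)
        out.append(
            BinnedProbability(
                bin_lo=float(lo),
                bin_hi=float(hi),
                found=found,
                probed=probed,
                probability=found / probed,
                jeffreys_lo=ci[0],
                jeffreys_hi=ci[1],
                drawn=probed >= min_probed,
            )
        )
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table.

    Two-sided by the classical minimum-likelihood rule: the sum of
    probabilities of all tables (at fixed margins) no more probable than
    the observed one. A zero margin gives p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(scistats.fisher_exact(t)[1])


def chi_squared_binned(found: Sequence[int], probed: Sequence[int]) -> tuple[float, float]:
    """Pearson chi-squared over a k×2 (found, not-found) table, df = k−1."""
    found = np.asarray(found, dtype=int)
    probed = np.asarray(probed, dtype=int)
    if found.size < 2:
        raise ValueError("need >= 2 bins")
    table = np.column_stack([found, probed - found])
    if (table.sum(axis=0) == 0).any() or (probed == 0).any():
        raise ValueError("expected count of zero in the contingency table")
    stat, p, _, _ = scistats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def benjamini_hochberg(
    p_values: Sequence[float], fdr: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR adjustment; returns (adjusted p values, rejections)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adjusted, reject


def compare_methods(counts: pd.DataFrame, fdr: float = 0.25) -> MethodComparison:
    """Compare connection probabilities measured by two methods per category.

    ``counts`` needs columns ``paired_found``, ``paired_probed``,
    ``opto_found``, ``opto_probed`` (one row per connection-class ×
    distance category). Per category: two-sided Fisher exact on the 2×2
    found/not-found table, then Benjamini–Hochberg across categories.
    Across categories: Pearson r between the two probability vectors and
    unweighted OLS of the optogenetic on the paired-recording
    probabilities with coefficient standard errors.
    """
    if len(counts) < 3:
        raise ValueError("need >= 3 categories")
    table = counts.copy()
    table["paired_probability"] = table["paired_found"] / table["paired_probed"]
    table["opto_probability"] = table["opto_found"] / table["opto_probed"]
    table["fisher_p"] = [
        fisher_exact_2x2(
            [
                [r.paired_found, r.paired_probed - r.paired_found],
                [r.opto_found, r.opto_probed - r.opto_found],
            ]
        )
        for r in table.itertuples()
    ]
    table["bh_p"], table["bh_reject"] = benjamini_hochberg(table["fisher_p"], fdr=fdr)

    r, p = scistats.pearsonr(table["paired_probability"], table["opto_probability"])
    ols = sm.OLS(
        table["opto_probability"], sm.add_constant(table["paired_probability"])
    ).fit()
    return MethodComparison(
        table=table,
        pearson_r=float(r),
        pearson_p=float(p),
        slope=float(ols.params.iloc[1]),
        slope_se=float(ols.bse.iloc[1]),
        intercept=float(ols.params.iloc[0]),
        intercept_se=float(ols.bse.iloc[0]),
    )


def effect_size_cohens_d(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Effect size d = (mean2 − mean1) / sqrt((SD1² + SD2²) / 2)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    if pooled == 0:
        return float("nan")
    return float((b.mean() - a.mean()) / pooled)


def dunns_test(
    groups: Mapping[str, Sequence[float]], p_adjust: str | None = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after a Kruskal–Wallis omnibus.

    Classical Dunn z statistics on pooled mid-ranks with a tie correction;
    two-sided normal p-values, Holm-adjusted by default.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(data)
    n = pooled.size
    ranks = scistats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for name, values in zip(names, data):
        stop = start + values.size
        mean_ranks[name] = float(np.mean(ranks[start:stop]))
        sizes[name] = values.size
        start = stop

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append(
            {"group1": a, "group2": b, "z": float(z), "p": float(2 * scistats.norm.sf(abs(z)))}
        )
    out = pd.DataFrame(rows)
    if p_adjust is not None and not out.empty:
        out["p_adjusted"] = multipletests(out["p"], method=p_adjust)[1]
    return out


def group_comparisons(
    groups: Mapping[str, Sequence[float]], p_adjust: str | None = "holm"
) -> tuple[float, pd.DataFrame]:
    """Kruskal–Wallis omnibus p-value plus Dunn's pairwise comparisons.

    Groups with fewer than two values are excluded with a warning.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    dropped = [k for k, v in usable.items() if v.size < 2]
    if dropped:
        warnings.warn(f"excluding group(s) of size < 2: {dropped}", stacklevel=2)
        usable = {k: v for k, v in usable.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 usable groups")
    omnibus = float(scistats.kruskal(*usable.values()).pvalue)
    return omnibus, dunns_test(usable, p_adjust=p_adjust)


def amplitude_distance_correlation(
    amplitudes: Sequence[float], distances: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between connection strength and a distance axis."""
    fn = scistats.spearmanr if method == "spearman" else scistats.pearsonr
    r, p = fn(np.asarray(distances, float), np.asarray(amplitudes, float))
    return float(r), float(p)
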