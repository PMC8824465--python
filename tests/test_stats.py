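"""Contingency tests, Jeffreys intervals, FDR, effect sizes, method comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scistats
from scipy.special import comb

from optomap import stats
from optomap.reference import METHOD_COMPARISON_COUNTS


class TestJeffreysInterval:
    def test_11_of_12_interval(self):
        """The 92% positive-predictive-value case: 11/12 -> (0.67, 0.99)."""
        lo, hi = stats.jeffreys_interval(11, 12)
        assert round(lo, 2) == 0.67
        assert round(hi, 2) == 0.99

    def test_boundary_conventions(self):
        lo, _ = stats.jeffreys_interval(0, 10)
        _, hi = stats.jeffreys_interval(10, 10)
        assert lo == 0.0
        assert hi == 1.0

    def test_matches_beta_quantiles(self):
        from scipy.stats import beta

        lo, hi = stats.jeffreys_interval(5, 20)
        assert lo == pytest.approx(beta.ppf(0.025, 5.5, 15.5), abs=1e-9)
        assert hi == pytest.approx(beta.ppf(0.975, 5.5, 15.5), abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            stats.jeffreys_interval(5, 4)

    def test_interval_shrinks_with_probed(self):
        widths = [
            np.diff(stats.jeffreys_interval(n // 5, n))[0]
            for n in [10, 50, 200, 1000]
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_coverage_on_simulated_binomials(self, rng):
        """Coverage stays >= 93% over a (p, n) grid with 10⁴ replicates."""
        for p in [0.05, 0.2, 0.5]:
            for n in [10, 40, 150]:
                found = rng.binomial(n, p, size=10_000)
                from scipy.stats import beta

                lo = beta.ppf(0.025, found + 0.5, n - found + 0.5)
                hi = beta.ppf(0.975, found + 0.5, n - found + 0.5)
                lo = np.where(found == 0, 0.0, lo)
                hi = np.where(found == n, 1.0, hi)
                coverage = np.mean((lo <= p) & (p <= hi))
                assert coverage >= 0.93


class TestFisherExact:
    def test_l5_interneuron_comparison(self):
        """Sparse L5 Pvalb vs common L5 Sst inhibition: p = 1.1e-3."""
        p = stats.fisher_exact_2x2([[2, 257], [16, 250]])
        assert p == pytest.approx(1.1e-3, abs=0.05e-3)

    def test_symmetric_table(self):
        assert stats.fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_zero_margin_convention(self):
        assert stats.fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    def test_transposition_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 15, (2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert stats.fisher_exact_2x2(t) == pytest.approx(
                stats.fisher_exact_2x2(t.T), abs=1e-12
            )

    def test_matches_hypergeometric_enumeration(self, rng):
        """Exhaustive minimum-likelihood enumeration oracle on small tables."""

        def oracle(t):
            a, b = t[0]
            c, d = t[1]
            r1, r2 = a + b, c + d
            c1 = a + c
            n = r1 + r2

            def prob(x):
                return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

            p_obs = prob(a)
            total = 0.0
            for x in range(max(0, c1 - r2), min(r1, c1) + 1):
                px = prob(x)
                if px <= p_obs * (1 + 1e-9):
                    total += px
            return min(total, 1.0)

        for _ in range(50):
            t = rng.integers(0, 12, (2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert stats.fisher_exact_2x2(t) == pytest.approx(oracle(t), abs=1e-9)


class TestChiSquared:
    def test_identical_proportions(self):
        stat, p = stats.chi_squared_binned([10, 20, 30], [100, 200, 300])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_statistic_p_identity_df2(self):
        """A statistic of 11.8 on a 3-bin table maps to p = 0.0027."""
        assert scistats.chi2.sf(11.8, 2) == pytest.approx(0.0027, abs=1e-4)

    def test_zero_expected_count_error(self):
        with pytest.raises(ValueError):
            stats.chi_squared_binned([0, 0], [10, 10])

    def test_two_bin_agreement_with_fisher_large_n(self):
        found = [300, 250]
        probed = [1000, 1000]
        _, p_chi = stats.chi_squared_binned(found, probed)
        p_fisher = stats.fisher_exact_2x2(
            [[found[0], probed[0] - found[0]], [found[1], probed[1] - found[1]]]
        )
        assert p_chi == pytest.approx(p_fisher, rel=0.15)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        adjusted, _ = stats.benjamini_hochberg([0.04])
        assert adjusted[0] == pytest.approx(0.04)

    def test_definition_based_oracle(self, rng):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(30):
            p = rng.random(rng.integers(1, 25))
            adjusted, _ = stats.benjamini_hochberg(p)
            np.testing.assert_allclose(adjusted, oracle(p), atol=1e-12)

    def test_monotone_and_idempotent(self, rng):
        p = np.sort(rng.random(15))
        adjusted, _ = stats.benjamini_hochberg(p)
        assert (np.diff(adjusted) >= -1e-12).all()
        twice, _ = stats.benjamini_hochberg(adjusted)
        once_again, _ = stats.benjamini_hochberg(adjusted)
        np.testing.assert_allclose(twice, once_again)


class TestCompareMethods:
    def test_identical_probabilities(self):
        counts = pd.DataFrame(
            {
                "paired_found": [5, 10, 20],
                "paired_probed": [50, 50, 50],
                "opto_found": [5, 10, 20],
                "opto_probed": [50, 50, 50],
            }
        )
        cmp = stats.compare_methods(counts)
        assert cmp.pearson_r == pytest.approx(1.0)
        assert cmp.slope == pytest.approx(1.0, abs=1e-9)
        assert cmp.intercept == pytest.approx(0.0, abs=1e-9)

    def test_published_cross_method_statistics(self):
        """The 14-category comparison: r = 0.74, slope 0.80, intercept 0.03."""
        cmp = stats.compare_methods(METHOD_COMPARISON_COUNTS)
        assert round(cmp.pearson_r, 2) == 0.74
        assert round(cmp.slope, 2) == 0.80
        assert round(cmp.intercept, 2) == 0.03
        assert round(cmp.slope_se, 2) == 0.21
        assert round(cmp.intercept_se, 2) == 0.06
        # the only category significant before correction loses significance
        smallest = cmp.table["fisher_p"].min()
        assert round(smallest, 2) == 0.03
        assert round(cmp.table.loc[cmp.table["fisher_p"].idxmin(), "bh_p"], 2) == 0.44


class TestEffectSize:
    def test_equal_means_zero(self):
        assert stats.effect_size_cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_closed_form_unit_effect(self, rng):
        a = rng.normal(1.0, 1.0, 2000)
        b = rng.normal(2.0, 1.0, 2000)
        d = stats.effect_size_cohens_d(a, b)
        se = np.sqrt(2 / 2000 + 1.0 / (2 * 2 * 2000))
        assert abs(d - 1.0) < 3 * se


class TestGroupComparisons:
    def test_identical_groups_high_p(self, rng):
        g = rng.normal(size=30)
        omnibus, dunns = stats.group_comparisons({"a": g, "b": g.copy(), "c": g.copy()})
        assert omnibus > 0.9
        assert (dunns["p"] > 0.9).all()

    def test_shifted_group_detected(self, rng):
        groups = {
            "a": rng.normal(0, 1, 40),
            "b": rng.normal(0, 1, 40),
            "c": rng.normal(2, 1, 40),
        }
        omnibus, dunns = stats.group_comparisons(groups)
        assert omnibus < 0.01
        row = dunns[(dunns["group1"] == "a") & (dunns["group2"] == "c")]
        assert row["p_adjusted"].iloc[0] < 0.01

    def test_small_group_excluded_with_warning(self, rng):
        with pytest.warns(UserWarning, match="size"):
            stats.group_comparisons(
                {"a": rng.normal(size=20), "b": rng.normal(size=20), "c": [1.0]}
            )

    def test_dunn_z_matches_definition(self, rng):
        """Dunn's z reproduces the hand-computed rank statistic (no ties)."""
        groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(1, 1, 15)}
        dunns = stats.dunns_test(groups, p_adjust=None)
        pooled = np.concatenate([groups["a"], groups["b"]])
        ranks = scistats.rankdata(pooled)
        n = pooled.size
        mean_a, mean_b = ranks[:12].mean(), ranks[12:].mean()
        se = np.sqrt(n * (n + 1) / 12.0 * (1 / 12 + 1 / 15))
        z_expected = (mean_a - mean_b) / se
        assert dunns["z"].iloc[0] == pytest.approx(z_expected, rel=1e-9)


class TestBinnedConnectionProbability:
    def _frame(self, pia, connected, artifact=None):
        n = len(pia)
        return pd.DataFrame(
            {
                "pre_pia_um": pia,
                "horizontal_offset_um": np.zeros(n),
                "distance_3d_um": pia,
                "connected": connected,
                "artifact_excluded": artifact if artifact is not None else [False] * n,
            }
        )

    def test_printed_ratio_example(self):
        """12 found / 205 probed -> 5.8% in one bin."""
        frame = self._frame([50.0] * 205, [True] * 12 + [False] * 193)
        bins = stats.binned_connection_probability(frame, axis="pia")
        assert len(bins) == 1
        assert bins[0].probability == pytest.approx(0.0585, abs=5e-4)
        assert bins[0].drawn

    def test_zero_found_boundary(self):
        frame = self._frame([50.0] * 50, [False] * 50)
        (b,) = stats.binned_connection_probability(frame, axis="pia")
        assert b.probability == 0.0
        assert b.jeffreys_lo == 0.0

    def test_artifact_pairs_leave_denominator(self):
        frame = self._frame(
            [50.0] * 20, [True] * 5 + [False] * 15, [False] * 10 + [True] * 10
        )
        (b,) = stats.binned_connection_probability(frame, axis="pia", min_probed=5)
        assert b.probed == 10

    def test_min_probed_drawing_rule(self):
        frame = self._frame([50.0] * 15, [True] * 3 + [False] * 12)
        (b,) = stats.binned_connection_probability(frame, axis="pia", min_probed=20)
        assert not b.drawn
        assert b.probed == 15  # counts still reported

    def test_synthetic_kernel_recovery(self, rng):
        """Binned estimates track a distance kernel within 3 binomial SDs."""
        n = 8000
        pia = rng.uniform(0, 600, n)
        p = 0.4 * np.exp(-pia / 300.0)
        conn = rng.random(n) < p
        frame = self._frame(pia, conn)
        for b in stats.binned_connection_probability(frame, axis="pia"):
            sel = (pia >= b.bin_lo) & (pia < b.bin_hi)
            p_true = p[sel].mean()
            se = np.sqrt(p_true * (1 - p_true) / b.probed)
            assert abs(b.probability - p_true) <= 3 * se
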