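"""Hill dose-response fitting, I-V regression and Mann-Whitney tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import megachan as mc
from megachan.fits import TitrationTable, hill_equation


def table(ca, y, sem=None, stat="Po"):
    ca = np.asarray(ca, float)
    return TitrationTable(
        ca_mm=ca,
        value=np.asarray(y, float),
        sem=None if sem is None else np.asarray(sem, float),
        n=np.full(ca.size, 4),
        statistic=stat,
    )


class TestHillFit:
    GRID = np.array([0.25, 0.5, 1.0, 2.0, 4.0])

    @pytest.mark.parametrize("gen_n", [1.0, 2.0])
    def test_exact_recovery_on_noise_free_data(self, gen_n):
        y = hill_equation(self.GRID, 1.0, 1.0, gen_n)
        fit = mc.hill_fit(table(self.GRID, y))
        assert fit.converged
        assert fit.n_hill == pytest.approx(gen_n, abs=1e-6)
        assert fit.k_half == pytest.approx(1.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_zero_ca_rows_are_excluded(self):
        ca = np.concatenate([[0.0], self.GRID])
        y = hill_equation(ca, 1.0, 1.0, 1.5)
        fit = mc.hill_fit(table(ca, y))
        assert fit.n_points == self.GRID.size
        assert fit.n_hill == pytest.approx(1.5, abs=1e-6)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            mc.hill_fit(table([0.5, 1.0, 2.0], [0.2, 0.4, 0.6]))

    def test_fixed_n_reduces_to_rectangular_hyperbola(self, rng):
        """With n pinned at 1 the fit coincides with an independent
        least-squares fit of y = y_max*ca/(k+ca)."""
        for _ in range(5):
            ymax, k = rng.uniform(0.5, 3.0), rng.uniform(0.3, 2.0)
            y = hill_equation(self.GRID, ymax, k, 1.0) * (
                1 + 0.02 * rng.standard_normal(self.GRID.size)
            )
            fit = mc.hill_fit(table(self.GRID, y), fix_n=1.0)

            def hyperbola(ca, a, b):
                return a * ca / (b + ca)

            popt, _ = optimize.curve_fit(
                hyperbola, self.GRID, y, p0=[y.max(), 1.0], maxfev=10000
            )
            assert fit.y_max == pytest.approx(popt[0], rel=1e-6)
            assert fit.k_half == pytest.approx(popt[1], rel=1e-6)
            assert fit.n_hill == 1.0

    def test_weighted_fit_honours_sems(self):
        """A grossly mis-measured point with a huge SEM is ignored by the
        weighted fit."""
        y = hill_equation(self.GRID, 1.0, 1.0, 1.5)
        y_bad = y.copy()
        y_bad[2] = 5.0
        sem = np.full(y.size, 0.01)
        sem[2] = 100.0
        fit = mc.hill_fit(table(self.GRID, y_bad, sem), weighting="sem")
        assert fit.n_hill == pytest.approx(1.5, abs=1e-3)

    @pytest.mark.parametrize("gen_n", [0.8, 1.0, 1.17, 1.37, 2.0])
    def test_recovery_across_hill_grid(self, gen_n, rng):
        """Median fitted n over repeated noisy draws stays within 10% of
        the generating coefficient."""
        fitted = []
        for _ in range(25):
            y = hill_equation(self.GRID, 1.0, 0.8, gen_n)
            noisy = y * (1 + 0.08 * rng.standard_normal(y.size))
            fitted.append(mc.hill_fit(table(self.GRID, noisy)).n_hill)
        assert np.median(fitted) == pytest.approx(gen_n, rel=0.10)


class TestIvFit:
    VOLTS = np.array([-80.0, -60.0, -40.0, -20.0, 0.0, 20.0])

    def test_exact_line_through_origin(self):
        pts = [(v, 0.5 * v) for v in self.VOLTS]
        fit = mc.iv_fit(pts)
        assert fit.slope_conductance == pytest.approx(500.0, rel=1e-9)
        assert fit.offset == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_shift_appears_as_intercept(self):
        pts = [(v, 0.5 * v + 13.0) for v in self.VOLTS]
        fit = mc.iv_fit(pts)
        assert fit.offset == pytest.approx(13.0, abs=1e-9)
        assert fit.slope_conductance == pytest.approx(500.0, rel=1e-9)
        assert np.allclose(fit.i_corrected_pa, 0.5 * self.VOLTS)

    def test_fixed_offset_mode(self):
        pts = [(v, 0.5 * v + 13.0) for v in self.VOLTS]
        fit = mc.iv_fit(pts, gradient_offset=13.0)
        assert fit.offset_mode == "fixed"
        assert fit.slope_conductance == pytest.approx(500.0, rel=1e-9)

    def test_noisy_slope_within_3se(self, rng):
        """Regression-theory oracle: SE(slope) = sigma/sqrt(sum (v-vbar)^2)."""
        sd = 2.0
        sxx = np.sum((self.VOLTS - self.VOLTS.mean()) ** 2)
        se_slope_ps = 1000.0 * sd / np.sqrt(sxx)
        for seed in range(10):
            noise = np.random.default_rng(seed).normal(0, sd, self.VOLTS.size)
            pts = list(zip(self.VOLTS, 0.5 * self.VOLTS + noise))
            fit = mc.iv_fit(pts)
            assert abs(fit.slope_conductance - 500.0) < 3 * se_slope_ps

    def test_degenerate_voltages_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            mc.iv_fit([(-60.0, 1.0), (-60.0, 2.0), (-60.0, 3.0)])
        with pytest.raises(ValueError, match=">= 3"):
            mc.iv_fit([(-60.0, 1.0), (20.0, 2.0)])


def brute_force_p(a, b):
    """Two-sided Mann-Whitney p by direct enumeration of all assignments
    of the pooled observations to the two groups."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = mc.mann_whitney(a, b).u_statistic
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        ranks = stats.rankdata(ga + gb)
        us.append(float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitney:
    def test_textbook_small_sample(self):
        res = mc.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(1 / 3)

    def test_identical_groups_with_ties(self):
        res = mc.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u_statistic == pytest.approx(4.5)
        assert res.method == "normal-approx"
        assert res.p_two_sided == pytest.approx(1.0)

    def test_complete_separation_n5(self):
        a = [101.0, 102.0, 103.0, 104.0, 105.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mc.mann_whitney(b, a)
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(2 / 252)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mc.mann_whitney([], [1.0])

    @pytest.mark.parametrize(
        "n1,n2", [(a, b) for a in range(1, 8) for b in range(a, 8) if a + b <= 8]
    )
    def test_exact_p_matches_brute_force(self, n1, n2, rng):
        """Enumeration over rank assignments agrees with a value-level
        permutation oracle for every small-sample size split."""
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
        a, b = list(vals[:n1]), list(vals[n1:])
        res = mc.mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(brute_force_p(a, b), abs=1e-12)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(10):
            a = list(rng.permutation(100)[:5] + rng.random(5))
            b = list(rng.permutation(100)[:6] + rng.random(6))
            mine = mc.mann_whitney(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_i_error_rate(self):
        """Same-distribution groups of 5: the exact test's true size at
        nominal 0.05 is 8/252 ~ 3.2% (the largest attainable level not
        exceeding 0.05), inside the 5% +/- 2% band; the empirical
        rejection rate over 1000 meta-replicates is consistent with that
        size within 3 binomial SEs."""
        from megachan.fits import _exact_null_counts

        counts = _exact_null_counts(5, 5)
        total = counts.sum()
        cdf = np.cumsum(counts) / total
        true_size = 0.0
        for u in range(counts.size):
            p = min(1.0, 2.0 * min(cdf[u], 1.0 - (cdf[u - 1] if u else 0.0)))
            if p <= 0.05:
                true_size += counts[u] / total
        assert 0.03 <= true_size <= 0.07
        rng = np.random.default_rng(123)
        rejections = sum(
            mc.mann_whitney(rng.standard_normal(5), rng.standard_normal(5)).p_two_sided
            <= 0.05
            for _ in range(1000)
        )
        se = np.sqrt(1000 * true_size * (1 - true_size))
        assert abs(rejections - 1000 * true_size) <= 3 * se


class TestCompareConditions:
    def _metric(self, psa, po, **cond):
        return mc.ChannelMetrics(
            psa=psa, po=po, g_mean=None, g_max=None, n_events=0,
            condition=mc.ConditionLabel(**cond), v_cis=-60.0,
        )

    def test_identical_groups_give_p_one(self):
        ms = [self._metric(1.0, 0.1, ca_mm=0.0) for _ in range(3)]
        ms += [self._metric(1.0, 0.1, ca_mm=3.0) for _ in range(3)]
        out = mc.compare_conditions(ms, grouping="ca_mm")
        assert (out["p"] == 1.0).all()
        assert (~out["adjusted"]).all()

    def test_three_groups_give_three_pairs_per_statistic(self):
        ms = []
        for ca, bz in [(0.0, 0.0), (3.0, 0.0), (3.0, 0.15)]:
            ms += [
                self._metric(float(i), 0.1 * i, ca_mm=ca, bz423_mm=bz)
                for i in range(1, 4)
            ]
        out = mc.compare_conditions(ms, grouping="label")
        assert len(out) == 6  # 3 pairs x 2 statistics
        assert set(out["statistic"]) == {"psa", "po"}

    def test_unknown_grouping_rejected(self):
        ms = [self._metric(1.0, 0.1, ca_mm=0.0), self._metric(2.0, 0.2, ca_mm=1.0)]
        with pytest.raises(ValueError, match="grouping"):
            mc.compare_conditions(ms, grouping="voltage")

    def test_control_vs_active_channels_detected(self):
        """5 silent control membranes vs 5 with an active channel: the PSA
        comparison reaches p <= 0.05 in >= 90% of meta-replicates."""
        from megachan.fixtures import fixed_po_scenario

        hits = 0
        n_meta = 20
        for meta in range(n_meta):
            ms = []
            for r in range(5):
                scen = fixed_po_scenario(500.0, 0.4, duration=5.0)
                seed_on = 1000 * meta + r
                tr = mc.simulate_scenario(scen, seed=seed_on)
                ms.append(mc.analyze_trace(tr))
            for r in range(5):
                rng = np.random.default_rng(5000 + 1000 * meta + r)
                noise = rng.standard_normal(50_000)
                tr = mc.CurrentTrace(
                    samples=noise, sampling_rate=10_000.0, v_cis=-60.0,
                    condition=mc.ConditionLabel(ca_mm=0.0),
                )
                ms.append(mc.analyze_trace(tr))
            out = mc.compare_conditions(ms, grouping="ca_mm")
            p = out.loc[out["statistic"] == "psa", "p"].iloc[0]
            if p <= 0.05:
                hits += 1
        assert hits >= 0.9 * n_meta
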