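"""Idealization, Po, conductances and amplitude histograms."""

import dataclasses

import numpy as np
import pytest

import megachan as mc
from megachan.fixtures import fig3b_scenario, fixed_po_scenario
from tests.conftest import make_trace


def square_trace(levels_and_ms, fs=10_000.0, v_cis=-60.0):
    """Unfiltered piecewise-constant trace from (level_pa, duration_ms)."""
    parts = [np.full(int(round(ms * 1e-3 * fs)), lv) for lv, ms in levels_and_ms]
    return make_trace(np.concatenate(parts), fs=fs, v_cis=v_cis)


class TestEstimateBaseline:
    def test_gaussian_noise_recovers_parameters(self):
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(100_000)
            b, s = mc.estimate_baseline(make_trace(x))
            assert abs(b) < 0.05
            assert s == pytest.approx(1.0, abs=0.1)

    def test_dominant_peak_nearest_zero_wins(self, rng):
        """Telegraph with Po 0.3: the baseline is the closed level at 0,
        not the open level at -30."""
        levels = np.where(rng.random(100_000) < 0.3, -30.0, 0.0)
        x = levels + rng.standard_normal(100_000)
        b, s = mc.estimate_baseline(make_trace(x))
        assert abs(b) < 0.2
        assert s == pytest.approx(1.0, abs=0.15)

    def test_constant_offset_shifts_baseline(self, rng):
        x = rng.standard_normal(50_000) - 9.0
        b, _ = mc.estimate_baseline(make_trace(x))
        assert b == pytest.approx(-9.0, abs=0.1)

    def test_never_closed_record_raises(self, rng):
        x = rng.standard_normal(50_000) - 30.0
        with pytest.raises(mc.BaselineNotFoundError):
            mc.estimate_baseline(make_trace(x))

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            mc.estimate_baseline(make_trace(np.zeros(500)))


class TestIdealize:
    def test_flat_trace_has_no_events(self):
        ideal = mc.idealize(make_trace(np.zeros(20_000)))
        assert len(ideal.events) == 0
        assert ideal.n_open == 0

    def test_square_wave_flags_match_exactly(self):
        pulses = [(0.0, 50), (-30.0, 50)] * 10
        tr = square_trace(pulses)
        ideal = mc.idealize(tr)
        expected = tr.samples < -15.0
        assert np.array_equal(ideal.open_flags, expected)
        assert len(ideal.events) == 10

    def test_open_time_monotone_in_threshold(self, rng):
        levels = np.where(rng.random(60_000) < 0.3, -8.0, 0.0)
        tr = make_trace(levels + rng.standard_normal(60_000))
        t3 = mc.idealize(tr, k_sigma=3.0).n_open
        t4 = mc.idealize(tr, k_sigma=4.0).n_open
        assert t4 <= t3


class TestComputePo:
    def test_all_closed_is_zero(self):
        tr = make_trace(np.zeros(20_000))
        assert mc.compute_po(mc.idealize(tr), tr.duration) == 0.0

    def test_half_duty_square_wave_is_exactly_half(self):
        tr = square_trace([(0.0, 50), (-30.0, 50)] * 10)
        assert mc.compute_po(mc.idealize(tr), tr.duration) == 0.5

    def test_two_state_simulation_recovers_stationary_po(self):
        """Mean Po estimate over 5 seeds matches the generating value
        within 3 SE of the mean."""
        # slow kinetics (50 ms dwells) so filter smear at event edges is a
        # negligible fraction of the open time
        target = 0.2
        scen = fixed_po_scenario(
            500.0, target, duration=60.0, sigma_white=1.0, line_amp=0.0,
            drift_amp=0.0, k_close=20.0,
        )
        pos = []
        for seed in range(5):
            tr = mc.simulate_scenario(scen, seed=seed)
            pos.append(mc.compute_po(mc.idealize(tr), tr.duration))
        se = np.std(pos, ddof=1) / np.sqrt(len(pos))
        assert np.mean(pos) == pytest.approx(target, abs=max(3 * se, 0.01))


class TestConductances:
    def test_steady_open_level_gives_500ps(self):
        tr = square_trace([(0.0, 100), (-30.0, 100), (0.0, 100)])
        ideal = mc.idealize(tr)
        assert mc.compute_g_mean(ideal, -60.0) == pytest.approx(500.0, rel=1e-9)

    def test_mixture_of_open_levels_averages(self):
        """Equal open time at -30 and -15 pA at -60 mV: mean open current
        -22.5 pA, G_mean 375 pS."""
        tr = square_trace([(0.0, 100), (-30.0, 100), (0.0, 100), (-15.0, 100)])
        ideal = mc.idealize(tr)
        assert mc.compute_g_mean(ideal, -60.0) == pytest.approx(375.0, rel=1e-9)

    def test_ohmic_scale_invariance(self):
        tr1 = square_trace([(0.0, 100), (-30.0, 100)])
        tr2 = square_trace([(0.0, 100), (-60.0, 100)])
        g1 = mc.compute_g_mean(mc.idealize(tr1), -60.0)
        g2 = mc.compute_g_mean(mc.idealize(tr2), -120.0)
        assert g1 == pytest.approx(g2, rel=1e-9)

    def test_zero_voltage_is_an_error(self):
        tr = square_trace([(0.0, 100), (-30.0, 100)])
        ideal = mc.idealize(tr)
        with pytest.raises(ValueError, match="0 mV"):
            mc.compute_g_mean(ideal, 0.0)
        with pytest.raises(ValueError, match="0 mV"):
            mc.compute_g_max(ideal, 0.0)

    def test_dwell_rule_rejects_flickers(self):
        """Stable -30 pA events pass the 10 ms rule; -60 pA 2 ms flickers
        do not: G_max 500 pS, or 1000 pS once the rule is lifted."""
        tr = square_trace(
            [(0.0, 50), (-30.0, 50), (0.0, 50), (-60.0, 2)] * 3 + [(0.0, 50)]
        )
        ideal = mc.idealize(tr)
        assert mc.compute_g_max(ideal, -60.0, min_dwell_ms=10.0) == pytest.approx(500.0)
        assert mc.compute_g_max(ideal, -60.0, min_dwell_ms=0.0) == pytest.approx(1000.0)

    def test_dwell_boundary_is_inclusive(self):
        """An event of exactly 10 ms qualifies; one sample shorter does not."""
        tr = square_trace([(0.0, 50), (-40.0, 10.0), (0.0, 50), (-50.0, 9.9), (0.0, 50)])
        ideal = mc.idealize(tr)
        assert mc.compute_g_max(ideal, -60.0, min_dwell_ms=10.0) == pytest.approx(
            1000.0 * 40.0 / 60.0
        )

    def test_no_qualifying_event_is_absent(self):
        tr = square_trace([(0.0, 50), (-40.0, 2), (0.0, 50)])
        ideal = mc.idealize(tr)
        assert mc.compute_g_max(ideal, -60.0, min_dwell_ms=10.0) is None

    def test_opposite_polarity_events_are_artifacts(self):
        """At -60 mV a positive-current event is excluded from
        conductances."""
        tr = square_trace([(0.0, 100), (+20.0, 50), (0.0, 100)])
        ideal = mc.idealize(tr)
        assert mc.compute_g_mean(ideal, -60.0) is None
        assert mc.compute_g_max(ideal, -60.0) is None


class TestAmplitudeHistogram:
    def test_noise_only_has_single_peak_at_zero(self, rng):
        tr = make_trace(rng.standard_normal(100_000) * 2.0)
        hist = mc.amplitude_histogram(tr, bin_width_pa=1.0)
        assert len(hist.peaks) == 1
        assert hist.peaks[0][0] == pytest.approx(0.0, abs=1.0)
        assert hist.counts.sum() == tr.n_samples

    @pytest.mark.parametrize("bin_width", [1.0, 0.5])
    def test_three_level_trace_shows_three_peaks(self, rng, bin_width):
        """Peaks at 0, -18 and -104 pA (closed, substate, full open at
        -80 mV), stable under bin halving."""
        n = 120_000
        u = rng.random(n)
        levels = np.select([u < 0.5, u < 0.8], [0.0, -18.0], default=-104.0)
        # hold each level for 10 samples to mimic dwell structure
        levels = np.repeat(levels[:: 10], 10)[:n]
        tr = make_trace(levels + rng.standard_normal(n), v_cis=-80.0)
        hist = mc.amplitude_histogram(tr, bin_width_pa=bin_width)
        assert len(hist.peaks) == 3
        found = sorted(p[0] for p in hist.peaks)
        for got, want in zip(found, [-104.0, -18.0, 0.0]):
            assert got == pytest.approx(want, abs=bin_width)


class TestAnalyzeTrace:
    def test_noise_only_metrics(self, rng):
        tr = make_trace(rng.standard_normal(60_000))
        m = mc.analyze_trace(tr)
        assert m.g_max is None
        assert m.po < 0.02
        # unfiltered unit-variance noise spreads over 0-5 kHz; the retained
        # 2-500 Hz band holds ~1/10 of it
        assert m.psa == pytest.approx(0.0992, rel=0.2)

    def test_determinism(self):
        tr = mc.simulate_scenario(fixed_po_scenario(300.0, 0.3, duration=5.0), seed=3)
        a = mc.analyze_trace(tr)
        b = mc.analyze_trace(tr)
        assert (a.psa, a.po, a.g_mean, a.g_max, a.n_events) == (
            b.psa, b.po, b.g_mean, b.g_max, b.n_events
        )

    def test_multistate_trace_shows_substate_peaks(self):
        scen = dataclasses.replace(fig3b_scenario(), duration=20.0)
        tr = mc.simulate_scenario(scen, seed=5)
        hist = mc.amplitude_histogram(tr, bin_width_pa=1.0)
        # closed peak plus at least two conducting-level peaks
        conducting = [p for p in hist.peaks if abs(p[0]) > 6.0]
        assert len(conducting) >= 2

    def test_baseline_shift_equivariance(self):
        tr = square_trace([(0.0, 80), (-30.0, 40)] * 5)
        shifted = tr.with_samples(tr.samples + 5.0)
        a = mc.analyze_trace(tr)
        b = mc.analyze_trace(shifted)
        assert b.baseline == pytest.approx(a.baseline + 5.0, abs=0.05)
        assert b.po == a.po
        assert b.g_mean == pytest.approx(a.g_mean, rel=1e-9)
        assert b.g_max == pytest.approx(a.g_max, rel=1e-9)

    def test_po_monotone_in_generating_po(self):
        """Across a 5-point grid of generating stationary Po with paired
        seeds, the estimate never decreases."""
        grid = [0.05, 0.1, 0.2, 0.3, 0.4]
        estimates = []
        for p in grid:
            scen = fixed_po_scenario(
                500.0, p, duration=20.0, sigma_white=1.0, line_amp=0.0,
                drift_amp=0.0, k_close=100.0,
            )
            tr = mc.simulate_scenario(scen, seed=77)
            estimates.append(mc.analyze_trace(tr).po)
        assert all(a <= b for a, b in zip(estimates, estimates[1:]))

    def test_g_max_at_least_g_mean(self):
        for seed in range(3):
            tr = mc.simulate_scenario(fig3b_scenario(duration=20.0), seed=seed)
            m = mc.analyze_trace(tr)
            assert m.g_max >= m.g_mean

    def test_voltage_equivariance(self):
        """The same gating at -60 and -80 mV yields equal conductances
        within noise tolerance."""
        results = []
        for v in (-60.0, -80.0):
            scen = dataclasses.replace(fig3b_scenario(duration=30.0), v_cis=v)
            tr = mc.simulate_scenario(scen, seed=13)
            results.append(mc.analyze_trace(tr))
        assert results[0].g_max == pytest.approx(results[1].g_max, rel=0.03)
        assert results[0].g_mean == pytest.approx(results[1].g_mean, rel=0.03)
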