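"""Twitch kinetics: trace analysis, 4PL, fatigue slopes, trend and f*."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from manakin.io_formats import ValidationError
from manakin.synthetic_data import simulate_force_trace
from manakin.twitch_kinetics import (
    FUSED_THRESHOLD,
    N_ANALYSIS_PULSES,
    FatigueSlope,
    StimulationTrain,
    compare_fatigue_slopes,
    compare_frequency_response,
    compare_half_relaxation,
    fatigue_comparison_table,
    fatigue_slope,
    fatigue_vs_frequency,
    four_pl,
    frequency_response_4pl,
    percent_relaxation_from_trace,
    phase_duration_test,
    stability_check,
)


def train(r, species="g", individual="g1", f=60.0, rep=1, **kw):
    return StimulationTrain(species=species, individual=individual,
                            frequency_hz=f, replicate=rep,
                            percent_relaxation=np.asarray(r, float), **kw)


class TestTrain:
    def test_analysis_pulses_first_eight(self):
        tr = train(np.arange(10.0, 110.0, 10.0) / 2)
        assert len(tr.analysis_pulses) == N_ANALYSIS_PULSES
        assert tr.mean_relaxation == pytest.approx(np.mean(np.arange(5, 45, 5.0)))

    def test_too_few_pulses(self):
        with pytest.raises(ValidationError):
            train([50.0] * 5)

    def test_negative_relaxation_rejected(self):
        with pytest.raises(ValidationError):
            train([50.0] * 7 + [-1.0])


class TestTraceAnalysis:
    def test_programmed_relaxation_recovered(self):
        r = np.array([90.0, 80.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0])
        trace = simulate_force_trace(r, frequency_hz=60.0)
        got = percent_relaxation_from_trace(trace)
        assert got.frequency_hz == pytest.approx(60.0, rel=1e-6)
        assert np.allclose(got.percent_relaxation, r, atol=1.0)

    def test_full_relaxation(self):
        r = np.full(8, 100.0)
        trace = simulate_force_trace(r, frequency_hz=40.0)
        got = percent_relaxation_from_trace(trace)
        assert np.allclose(got.percent_relaxation, 100.0, atol=1.0)

    def test_near_fused(self):
        r = np.full(8, 5.0)
        trace = simulate_force_trace(r, frequency_hz=80.0)
        got = percent_relaxation_from_trace(trace)
        assert np.allclose(got.percent_relaxation, 5.0, atol=1.0)

    def test_baseline_required(self):
        trace = simulate_force_trace(np.full(8, 50.0), frequency_hz=50.0)
        trace.time_s = trace.time_s - 1.0  # onsets now before every sample? no:
        # shift onsets to the very start so no pre-train samples remain
        trace.stim_times_s = trace.stim_times_s - trace.stim_times_s[0] \
            + trace.time_s[0]
        with pytest.raises(ValidationError, match="baseline"):
            percent_relaxation_from_trace(trace)


class TestFourPL:
    def test_shape(self):
        assert four_pl(95.0, 100, 0, 0.12, 95.0) == pytest.approx(50.0)
        assert four_pl(-1e9, 100, 0, 0.12, 95.0) == pytest.approx(100.0)
        assert four_pl(1e9, 100, 0, 0.12, 95.0) == pytest.approx(0.0)

    def _trains_from_curve(self, a, d, b, c, freqs, inds=3):
        out = []
        for i in range(inds):
            for f in freqs:
                out.append(train(np.full(10, four_pl(f, a, d, b, c)),
                                 individual=f"g{i}", f=f))
        return out

    def test_exact_recovery_noise_free(self):
        a, d, b, c = 98.0, 2.0, 0.15, 72.0
        freqs = [30, 45, 60, 72, 85, 100]
        fit = frequency_response_4pl(self._trains_from_curve(a, d, b, c, freqs))
        assert fit.params == pytest.approx([a, d, b, c], abs=1e-4)
        assert fit.f50 == pytest.approx(c, abs=1e-4)
        assert fit.sse == pytest.approx(0.0, abs=1e-8)
        assert fit.monotone
        assert not fit.f50_extrapolated

    def test_replicates_averaged_before_fit(self):
        a, d, b, c = 100.0, 0.0, 0.2, 60.0
        freqs = [40, 55, 70, 85]
        trains = []
        for f in freqs:
            level = four_pl(f, a, d, b, c)
            # two replicates whose mean is exactly on the curve
            trains.append(train(np.full(10, level + 5), f=f, rep=1))
            trains.append(train(np.full(10, max(level - 5, 0.0)), f=f, rep=2))
        fit = frequency_response_4pl(trains)
        assert len(fit.individual_means) == 4

    def test_needs_four_frequencies(self):
        with pytest.raises(ValidationError):
            frequency_response_4pl(self._trains_from_curve(
                100, 0, 0.1, 60, [40, 60, 80]))

    def test_extrapolated_f50_flagged(self):
        with pytest.warns(UserWarning, match="outside"):
            fit = frequency_response_4pl(self._trains_from_curve(
                100, 0, 0.05, 140, [30, 50, 70, 90]))
        assert fit.f50_extrapolated

    def test_species_comparison_null(self):
        rng = np.random.default_rng(0)
        freqs = [30, 50, 70, 90]

        def noisy(species):
            return [
                train(np.full(10, four_pl(f, 100, 0, 0.12, 60)
                              + rng.normal(0, 2)),
                      species=species, individual=f"{species}{i}", f=f)
                for i in range(4) for f in freqs
            ]

        F, dfs, p = compare_frequency_response(noisy("a"), noisy("b"))
        assert dfs == (4, 24)
        assert p > 0.01

    def test_half_relaxation_comparison_detects_shift(self):
        fit_a = frequency_response_4pl(self._trains_from_curve(
            100, 0, 0.12, 90, [30, 50, 70, 90, 110], inds=4))
        fit_b = frequency_response_4pl(self._trains_from_curve(
            100, 0, 0.12, 60, [30, 45, 60, 75, 90], inds=4))
        F, dfs, p = compare_half_relaxation(fit_a, fit_b)
        assert dfs == (1, fit_a.n + fit_b.n - 8)
        assert p < 0.05


class TestFatigueSlopes:
    def test_flat_train_slope_zero(self):
        fs = fatigue_slope([train(np.full(10, 70.0))])
        assert fs.slope == pytest.approx(0.0, abs=1e-12)
        assert fs.dfs == (1, 6)
        assert not fs.fused

    def test_programmed_slope_exact(self):
        r = 90.0 - 5.0 * np.arange(10)
        fs = fatigue_slope([train(r)])
        assert fs.slope == pytest.approx(-5.0, abs=1e-10)
        assert fs.se == pytest.approx(0.0, abs=1e-10)

    def test_replicates_then_individuals_averaging(self):
        # individual A: two replicates straddling a line; individual B flat.
        rA1 = 80.0 - 4.0 * np.arange(10) + 3.0
        rA2 = 80.0 - 4.0 * np.arange(10) - 3.0
        rB = np.full(10, 40.0)
        fs = fatigue_slope([
            train(rA1, individual="A", rep=1),
            train(rA2, individual="A", rep=2),
            train(rB, individual="B"),
        ])
        assert fs.slope == pytest.approx(-2.0, abs=1e-10)  # mean of -4 and 0

    def test_fused_flag(self):
        fs = fatigue_slope([train(np.full(10, FUSED_THRESHOLD - 1.0))])
        assert fs.fused

    def test_mixed_frequencies_rejected(self):
        with pytest.raises(ValidationError):
            fatigue_slope([train(np.full(10, 50.0), f=60),
                           train(np.full(10, 50.0), f=70)])

    def test_comparison_detects_slope_difference(self):
        a = fatigue_slope([train(90.0 - 5.0 * np.arange(10), species="a")])
        b = fatigue_slope([train(np.full(10, 60.0), species="b", individual="b1")])
        F, dfs, p = compare_fatigue_slopes(a, b)
        assert dfs == (1, 12)
        assert p < 1e-6

    def test_comparison_requires_same_frequency(self):
        a = fatigue_slope([train(np.full(10, 60.0), f=60)])
        b = fatigue_slope([train(np.full(10, 60.0), f=70)])
        with pytest.raises(ValidationError):
            compare_fatigue_slopes(a, b)

    def test_comparison_table_layout(self):
        ta = [train(np.full(10, 60.0), species="a", f=f) for f in (50, 60, 70)]
        tb = [train(np.full(10, 60.0), species="b", individual="b1", f=f)
              for f in (60, 70, 80)]
        tab = fatigue_comparison_table(ta, tb)
        assert list(tab.frequency_hz) == [50, 60, 70, 80]
        shared = tab[tab.frequency_hz.isin([60, 70])]
        assert shared["F_comparison"].notna().all()
        assert tab.loc[tab.frequency_hz == 50, "slope_b"].isna().all()


class TestFatigueTrend:
    def test_all_zero_slopes_no_crossing(self):
        trend = fatigue_vs_frequency({f: 0.0 for f in (30, 50, 70, 90)})
        assert trend.gamma == pytest.approx(0.0)
        assert trend.fstar is None

    def test_linear_slopes_grid_oracle(self):
        """s(f) = 3 - 0.05 f with tiny noise: f* matches a dense-grid scan
        of the same band function."""
        rng = np.random.default_rng(2)
        freqs = np.arange(30, 101, 10)
        slopes = {float(f): 3 - 0.05 * f + rng.normal(0, 1e-3) for f in freqs}
        trend = fatigue_vs_frequency(slopes)
        grid = np.linspace(0, 100, 400_001)
        upper = trend.band(grid)[2]
        crossing = grid[np.argmax(upper < 0)]
        assert trend.fstar == pytest.approx(crossing, abs=1e-3)
        # and near the closed-form mean-line crossing of 60 Hz
        assert trend.fstar == pytest.approx(60.0, abs=0.5)

    def test_band_is_confidence_not_prediction(self):
        freqs = np.array([30.0, 50.0, 70.0, 90.0])
        slopes = np.array([0.5, 0.1, -0.6, -1.0])
        trend = fatigue_vs_frequency(dict(zip(freqs, slopes)))
        lo, mid, hi = trend.band(freqs)
        n = len(freqs)
        fbar = freqs.mean()
        sxx = np.sum((freqs - fbar) ** 2)
        tcrit = st.t.ppf(0.975, n - 2)
        half = tcrit * trend.resid_sd * np.sqrt(1 / n + (freqs - fbar) ** 2 / sxx)
        assert hi == pytest.approx(mid + half)
        assert lo == pytest.approx(mid - half)

    def test_regression_statistics(self):
        freqs = np.array([30.0, 50.0, 70.0, 90.0, 110.0])
        slopes = -0.1 * freqs + 2.0 + np.array([0.05, -0.02, 0.01, -0.04, 0.0])
        trend = fatigue_vs_frequency(dict(zip(freqs, slopes)))
        res = st.linregress(freqs, slopes)
        assert trend.gamma == pytest.approx(res.slope)
        assert trend.F == pytest.approx((res.slope / res.stderr) ** 2)
        assert trend.dfs == (1, 3)
        assert trend.r2 == pytest.approx(res.rvalue ** 2)

    def test_needs_four_frequencies(self):
        with pytest.raises(ValidationError):
            fatigue_vs_frequency({30.0: 0.0, 50.0: -1.0, 70.0: -2.0})


class TestPhasesAndStability:
    def test_flat_phases_not_significant(self):
        rows = []
        rng = np.random.default_rng(3)
        for rep in (1, 2):
            for k in range(1, 11):
                rows.append(dict(species="g", frequency_hz=60.0, replicate=rep,
                                 pulse=k,
                                 shortening_ms=5.0 + rng.normal(0, 0.01),
                                 lengthening_ms=6.0 + rng.normal(0, 0.01)))
        out = phase_duration_test(pd.DataFrame(rows))
        assert set(out.phase) == {"shortening", "lengthening"}
        assert (out.p > 0.01).all()

    def test_trending_phase_detected(self):
        rows = [dict(species="g", frequency_hz=60.0, replicate=1, pulse=k,
                     shortening_ms=5.0 + 0.5 * k + 0.001 * (-1) ** k,
                     lengthening_ms=6.0)
                for k in range(1, 9)]
        out = phase_duration_test(pd.DataFrame(rows))
        short = out[out.phase == "shortening"].iloc[0]
        assert short.slope == pytest.approx(0.5, abs=0.01)
        assert short.p < 1e-6

    def test_stability_identical_is_stable(self):
        first = [train(np.full(10, 60.0), individual=f"g{i}") for i in range(4)]
        t, p, n = stability_check(first, [train(np.full(10, 60.0),
                                                individual=f"g{i}", rep=2)
                                          for i in range(4)])
        assert (t, p, n) == (0.0, 1.0, 4)

    def test_stability_paired_t_closed_form(self):
        """Constant per-individual difference d with alternating sign noise:
        compare against scipy's paired t directly."""
        first = [train(np.full(10, 60.0 + i), individual=f"g{i}")
                 for i in range(5)]
        repeat = [train(np.full(10, 57.0 + i + 0.1 * (-1) ** i),
                        individual=f"g{i}", rep=2) for i in range(5)]
        t, p, n = stability_check(first, repeat)
        xa = np.array([60.0 + i for i in range(5)])
        xb = np.array([57.0 + i + 0.1 * (-1) ** i for i in range(5)])
        t_ref, p_ref = st.ttest_rel(xa, xb)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)
        assert n == 5

    def test_unpaired_dropped_with_warning(self):
        first = [train(np.full(10, 60.0), individual="g1"),
                 train(np.full(10, 61.0), individual="g2"),
                 train(np.full(10, 63.0), individual="g3")]
        repeat = [train(np.full(10, 59.0), individual="g1", rep=2),
                  train(np.full(10, 62.0), individual="g2", rep=2),
                  train(np.full(10, 70.0), individual="g9", rep=2)]
        with pytest.warns(UserWarning, match="unpaired"):
            t, p, n = stability_check(first, repeat)
        assert n == 2
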