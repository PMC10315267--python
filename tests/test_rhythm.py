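import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from zeitprot.rhythm import (
    AcrophaseSeries,
    LuminescenceTrace,
    compare_acrophases,
    compare_periods,
    daily_acrophase,
    fit_fft_nlls,
    rayleigh,
)
from tests.conftest import cosine_trace


class TestFftNlls:
    @pytest.mark.parametrize("period", [20.0, 24.0, 28.0])
    def test_noiseless_cosine_recovered_to_three_sig_figs(self, period):
        fit = fit_fft_nlls(cosine_trace(period_h=period))
        assert fit.rhythmic
        assert fit.period_h == pytest.approx(period, rel=5e-4)
        assert fit.amplitude == pytest.approx(2.0, rel=5e-4)
        assert fit.acrophase_ct == pytest.approx(4.0, abs=0.01)
        assert fit.rae < 0.01

    def test_constant_trace_not_rhythmic(self):
        t = np.arange(0.0, 120.0, 1.0)
        fit = fit_fft_nlls(LuminescenceTrace(times=t, values=np.full_like(t, 7.0)))
        assert not fit.rhythmic and math.isnan(fit.period_h)

    def test_short_span_is_an_error(self):
        with pytest.raises(ValueError, match="span"):
            fit_fft_nlls(cosine_trace(span_h=25.0))

    def test_damped_noisy_period_recovered(self):
        t = np.arange(0.0, 120.0, 1.0)
        periods = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 5 + 2 * np.exp(-t / 96) * np.cos(2 * np.pi * (t - 4) / 26.5)
            y = y + rng.normal(0, 0.1, len(t))  # sigma = 5% of amplitude
            fit = fit_fft_nlls(LuminescenceTrace(times=t, values=y))
            assert fit.rhythmic
            periods.append(fit.period_h)
        assert np.mean(periods) == pytest.approx(26.5, abs=0.2)

    def test_pure_noise_has_high_rae(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 120.0, 1.0)
        fit = fit_fft_nlls(LuminescenceTrace(times=t, values=rng.normal(10, 1, len(t))))
        assert fit.rae > 0.2

    def test_trend_does_not_masquerade_as_rhythm(self):
        trace = cosine_trace()
        drifting = LuminescenceTrace(times=trace.times, values=trace.values + 0.05 * trace.times)
        fit = fit_fft_nlls(drifting)
        assert fit.period_h == pytest.approx(24.0, rel=1e-3)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-2)


class TestDailyAcrophase:
    def test_fixed_peak_every_day(self):
        trace = cosine_trace(period_h=24.0, phase_h=2.0, span_h=96.0)
        acros = daily_acrophase(trace)
        assert [d for d, _ in acros] == [0, 1, 2, 3]
        for _, a in acros:
            assert a == pytest.approx(2.0, abs=0.5)

    def test_drifting_peak_advances_daily(self):
        trace = cosine_trace(period_h=25.0, phase_h=2.0, span_h=120.0)
        acros = dict(daily_acrophase(trace))
        for day in range(1, 4):
            assert acros[day] - acros[0] == pytest.approx(day * 1.0, abs=0.6)

    def test_flat_window_flagged_nan(self):
        t = np.arange(0.0, 48.0, 1.0)
        y = np.concatenate([np.full(24, 5.0), 5.0 + np.cos(2 * np.pi * (t[:24] - 6) / 24)])
        acros = dict(daily_acrophase(LuminescenceTrace(times=t, values=y), smooth_window_h=1.0))
        assert math.isnan(acros[0]) and not math.isnan(acros[1])

    def test_windows_anchor_at_segment_start(self):
        trace = cosine_trace(period_h=24.0, phase_h=2.0, span_h=120.0)
        trace.segments = [(0.0, 48.0, "LL"), (48.0, 120.0, "temp_cycle")]
        acros = daily_acrophase(trace, segment_label="temp_cycle")
        assert [d for d, _ in acros] == [0, 1, 2]
        for _, a in acros:
            assert a == pytest.approx(2.0, abs=0.5)  # 48 h is a whole number of cycles

    def test_noisy_recovery_within_half_hour(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            trace = cosine_trace(period_h=24.0, phase_h=7.0, span_h=96.0)
            noisy = LuminescenceTrace(
                times=trace.times, values=trace.values * rng.normal(1, 0.05, len(trace.times))
            )
            errs.extend(a - 7.0 for _, a in daily_acrophase(noisy))
        assert abs(np.mean(errs)) < 0.5


class TestRayleigh:
    def test_identical_phases_give_R_one(self):
        r, mean_phase, p = rayleigh([3.0] * 8)
        assert r == pytest.approx(1.0)
        assert mean_phase == pytest.approx(3.0)
        assert p < 1e-4

    def test_antipodal_phases_give_R_zero(self):
        r, _, p = rayleigh([0.0, 12.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_uniform_grid_gives_R_zero(self):
        r, _, _ = rayleigh([k * 3.0 for k in range(8)])
        assert r == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        phases=st.lists(st.floats(0, 24, allow_nan=False), min_size=1, max_size=12),
        shift=st.floats(-48, 48, allow_nan=False),
    )
    def test_property_rotation_invariant_and_bounded(self, phases, shift):
        r0, _, p0 = rayleigh(phases)
        r1, _, p1 = rayleigh([(p + shift) % 24 for p in phases])
        assert 0 <= r0 <= 1 + 1e-12
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        phases = rng.uniform(0, 24, 10)
        r0, _, p0 = rayleigh(phases)
        r1, _, p1 = rayleigh((phases + 5.37) % 24)
        assert r1 == pytest.approx(r0) and p1 == pytest.approx(p0)
        assert 0 <= r0 <= 1

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            rayleigh([])


class TestComparePeriods:
    def test_identical_groups_share_a_letter(self):
        F, p, tukey, letters = compare_periods({"a": [24.0, 24.0], "b": [24.0, 24.0]})
        assert F == 0.0 and p == 1.0
        assert letters["a"] == letters["b"] == "a"

    def test_separated_group_gets_distinct_letter(self):
        groups = {
            "wt": [24.0, 24.05, 23.95],
            "rescue": [24.01, 24.06, 23.96],
            "mutant": [27.0, 27.05, 26.95],
        }
        F, p, tukey, letters = compare_periods(groups)
        assert p < 1e-6
        assert letters["wt"] == letters["rescue"]
        assert letters["mutant"] != letters["wt"]

    def test_tukey_agrees_with_permutation_approximation(self, rng):
        # balanced 3 x n=5 design; permutation null of the studentized range
        groups = {
            "a": rng.normal(24.0, 0.4, 5),
            "b": rng.normal(24.4, 0.4, 5),
            "c": rng.normal(24.6, 0.4, 5),
        }
        _, _, tukey, _ = compare_periods(groups)
        names = list(groups)
        pooled = np.concatenate([groups[g] for g in names])
        n = 5
        obs_q = {}
        msw = np.mean([np.var(groups[g], ddof=1) for g in names])
        for i, j in itertools.combinations(range(3), 2):
            obs_q[(i, j)] = abs(groups[names[i]].mean() - groups[names[j]].mean()) / math.sqrt(msw / n)
        exceed = {k: 0 for k in obs_q}
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled).reshape(3, n)
            msw_p = perm.var(axis=1, ddof=1).mean()
            means = perm.mean(axis=1)
            q_max = (means.max() - means.min()) / math.sqrt(msw_p / n)
            for k, q in obs_q.items():
                exceed[k] += q_max >= q
        for row in tukey.itertuples():
            i, j = names.index(row.group_a), names.index(row.group_b)
            assert row.p_adj == pytest.approx(exceed[(i, j)] / n_perm, abs=0.02)

    def test_validation(self):
        with pytest.raises(ValueError):
            compare_periods({"a": [24.0, 24.1]})
        with pytest.raises(ValueError, match="fewer than two"):
            compare_periods({"a": [24.0, 24.1], "b": [24.0]})


class TestCompareAcrophases:
    def make_series(self, offsets_by_day, sd=0.3, n=16, seed=0):
        rng = np.random.default_rng(seed)
        data = {"wt": {}, "mutant": {}}
        for day, off in enumerate(offsets_by_day):
            data["wt"][day] = (4.0 + rng.normal(0, sd, n)) % 24
            data["mutant"][day] = (4.0 + off + rng.normal(0, sd, n)) % 24
        return AcrophaseSeries(cycle_h=24.0, data=data)

    def test_identical_genotype_resyncs_immediately(self):
        rng = np.random.default_rng(3)
        shared = {d: (4.0 + rng.normal(0, 0.3, 8)) % 24 for d in range(4)}
        series = AcrophaseSeries(cycle_h=24.0, data={"wt": dict(shared), "mut": {d: v.copy() for d, v in shared.items()}})
        table, resync = compare_acrophases(series, "wt")
        assert (table["p"] == 1.0).all()
        assert resync["mut"] == 0

    def test_decaying_offset_resynchronizes_by_day_three(self):
        # 6 h initial offset decaying 2 h/day: offsets 6, 4, 2, 0, 0; the
        # typical run resynchronizes on the first zero-offset day (day 3),
        # with occasional day-4/never calls from 5% null rejections
        days = []
        for seed in range(11):
            series = self.make_series([6.0, 4.0, 2.0, 0.0, 0.0], seed=seed)
            _, resync = compare_acrophases(series, "wt")
            days.append(5 if resync["mutant"] is None else resync["mutant"])
        assert np.median(days) == 3

    def test_constant_offset_never_resynchronizes(self):
        series = self.make_series([6.0] * 5)
        _, resync = compare_acrophases(series, "wt")
        assert resync["mutant"] is None

    def test_untestable_day_flagged(self):
        series = AcrophaseSeries(
            cycle_h=24.0,
            data={
                "wt": {0: np.array([4.0, 4.2]), 1: np.array([4.0, 4.2])},
                "mut": {0: np.array([5.0]), 1: np.array([5.0, 5.2])},
            },
        )
        table, _ = compare_acrophases(series, "wt")
        day0 = table[table["day"] == 0].iloc[0]
        assert not day0["testable"] and math.isnan(day0["p"])

    def test_wraparound_phases_compared_on_circle(self):
        # phases straddling midnight: 23.8 vs 0.2 differ by 0.4 h, not 23.6
        rng = np.random.default_rng(5)
        data = {
            "wt": {0: (23.8 + rng.normal(0, 0.1, 8)) % 24},
            "mut": {0: (0.2 + rng.normal(0, 0.1, 8)) % 24},
        }
        table, _ = compare_acrophases(AcrophaseSeries(cycle_h=24.0, data=data), "wt")
        assert abs(table.iloc[0]["mean_offset_h"]) < 1.0
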