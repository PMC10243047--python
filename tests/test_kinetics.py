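"""Growth fitting, metabolite mass balance and medium-exchange accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bioshear as bs
from bioshear.kinetics import ML_PER_L


def make_series(times, mu=0.028, cx0=1e5, metabolites=None, events=()):
    t = np.asarray(times, dtype=float)
    return bs.CultureTimeSeries(
        times=t,
        viable_density=cx0 * np.exp(mu * t),
        metabolites=metabolites or {},
        exchange_events=tuple(events),
    )


class TestGrowthFit:
    def test_noiseless_recovery_is_exact(self):
        fit = bs.fit_growth(make_series([0, 72, 120, 168]))
        assert fit.mu == pytest.approx(0.028, rel=1e-12)
        assert fit.initial_density == pytest.approx(1e5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @given(
        mu=st.floats(-0.1, 0.1),
        n_extra=st.integers(1, 6),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_noiseless_recovery_any_rate_and_sampling(self, mu, n_extra, seed):
        rng = np.random.default_rng(seed)
        t = np.concatenate([[0.0], np.cumsum(rng.uniform(1.0, 48.0, size=n_extra))])
        fit = bs.fit_growth(make_series(t, mu=mu, cx0=2e5))
        assert fit.mu == pytest.approx(mu, abs=1e-9)
        assert fit.initial_density == pytest.approx(2e5, rel=1e-9)

    def test_constant_series_gives_zero_rate(self):
        fit = bs.fit_growth(make_series([0, 24, 48], mu=0.0))
        assert fit.mu == pytest.approx(0.0, abs=1e-15)

    def test_too_few_points_rejected(self):
        with pytest.raises(bs.InvalidInputError):
            bs.fit_growth(make_series([0.0]))

    def test_nonpositive_density_rejected(self):
        with pytest.raises(bs.InvalidInputError):
            bs.CultureTimeSeries(times=np.array([0.0, 24.0]), viable_density=np.array([1e5, 0.0]))

    def test_predict_density(self):
        fit = bs.GrowthFit(mu=0.028, initial_density=1e5, r_squared=1.0)
        assert bs.predict_density(fit, 0.0) == pytest.approx(1e5)
        flat = bs.GrowthFit(mu=0.0, initial_density=1e5, r_squared=1.0)
        assert np.allclose(bs.predict_density(flat, [0, 100, 500]), 1e5)
        t_star = np.log(27.4) / 0.028
        assert bs.predict_density(fit, t_star) == pytest.approx(2.74e6, rel=1e-12)


class TestFoldExpansion:
    @pytest.mark.parametrize(
        "initial, final, expected",
        [(1e5, 2.74e6, 27.4), (1e5, 2.45e6, 24.5), (3.3e5, 3.3e5, 1.0)],
    )
    def test_worked_examples(self, initial, final, expected):
        assert bs.fold_expansion(initial, final) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(bs.InvalidInputError):
            bs.fold_expansion(0.0, 1e6)


class TestRSquared:
    def test_perfect_and_mean_predictions(self):
        obs = [1.0, 2.0, 3.0]
        assert bs.r_squared(obs, obs) == pytest.approx(1.0)
        assert bs.r_squared(obs, [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_three_point_hand_example(self):
        assert bs.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(bs.UndefinedStatisticError):
            bs.r_squared([2.0, 2.0], [1.0, 2.0])


class TestExchangeCorrection:
    def test_no_events_is_identity_minus_baseline(self):
        series = make_series([0, 48, 96], metabolites={"glucose": np.array([2.0, 1.5, 1.1])})
        corrected = bs.apply_exchange_correction(series)
        assert np.allclose(corrected.metabolites["glucose"], [0.0, -0.5, -0.9])

    def test_single_event_baseline_reset(self):
        # f=0.5, C(tau-)=1.0, fresh=2.0 -> post-event baseline 1.5; a sample
        # at 1.4 g/l afterwards means only 0.1 g/l was consumed post-event
        ev = bs.ExchangeEvent(time=48.0, fraction=0.5, fresh={"glucose": 2.0})
        series = make_series(
            [0, 48, 96],
            metabolites={"glucose": np.array([2.0, 1.0, 1.4])},
            events=[ev],
        )
        corrected = bs.apply_exchange_correction(series)
        assert np.allclose(corrected.metabolites["glucose"], [0.0, -1.0, -1.1])

    def test_conservation_against_explicit_bookkeeping(self):
        # oracle: track grams in the vessel explicitly through each event
        times = np.array([0.0, 24.0, 72.0, 120.0, 168.0])
        conc = np.array([2.0, 1.8, 1.5, 1.2, 0.7])
        events = [
            bs.ExchangeEvent(time=24.0, fraction=0.5, fresh={"glucose": 2.0}),
            bs.ExchangeEvent(time=120.0, fraction=0.3, fresh={"glucose": 2.0}),
        ]
        series = bs.CultureTimeSeries(
            times=times,
            viable_density=1e5 * np.exp(0.02 * times),
            metabolites={"glucose": conc},
            exchange_events=tuple(events),
        )
        # explicit ledger: consumption per segment = C(start baseline) - C(end)
        c = conc[0]
        consumed = 0.0
        for t0, t1, c1 in [(0, 24, 1.8), (24, 72, 1.5), (72, 120, 1.2), (120, 168, 0.7)]:
            consumed += c - c1
            ev = next((e for e in events if e.time == t1), None)
            c = (1 - ev.fraction) * c1 + ev.fraction * 2.0 if ev else c1
        corrected = bs.apply_exchange_correction(series)
        assert corrected.metabolites["glucose"][-1] == pytest.approx(-consumed, rel=1e-12)

    def test_event_outside_range_rejected(self):
        with pytest.raises(bs.InvalidInputError):
            make_series(
                [0, 48],
                metabolites={"glucose": np.array([2.0, 1.5])},
                events=[bs.ExchangeEvent(time=100.0, fraction=0.5)],
            )

    @given(split=st.floats(10.0, 150.0))
    @settings(max_examples=25, deadline=None)
    def test_total_change_independent_of_neutral_event_splits(self, split):
        # an event replacing medium with identical-concentration medium must
        # not change the accounted totals, wherever it is inserted
        times = np.array([0.0, 80.0, 160.0])
        conc = np.array([2.0, 1.4, 0.9])
        base = make_series(times, metabolites={"glucose": conc})
        c_at_split = float(np.interp(split, times, conc))
        ev = bs.ExchangeEvent(time=split, fraction=0.5, fresh={"glucose": c_at_split})
        with_ev = make_series(times, metabolites={"glucose": conc}, events=[ev])
        a = bs.apply_exchange_correction(base).metabolites["glucose"][-1]
        b = bs.apply_exchange_correction(with_ev).metabolites["glucose"][-1]
        assert b == pytest.approx(a, abs=1e-12)


class TestSpecificRate:
    def test_constant_density_direct_arithmetic(self):
        times = np.array([0.0, 48.0])
        series = bs.CultureTimeSeries(
            times=times,
            viable_density=np.array([1e6, 1e6]),
            metabolites={"glucose": np.array([2.0, 1.5])},
        )
        rates = bs.specific_metabolite_rate(series, "glucose")
        # 0.5 g/l over 48 h at 1e6 cells/ml = 1e9 cells/l
        assert rates.interval_rates[0] == pytest.approx(-0.5 / (48 * 1e6 * ML_PER_L), rel=1e-12)
        assert rates.rate == pytest.approx(1.0417e-11, rel=0.01)
        assert rates.direction == "consumption"

    def test_zero_change_zero_rate(self):
        series = make_series([0, 48], metabolites={"glucose": np.array([2.0, 2.0])})
        assert bs.specific_metabolite_rate(series, "glucose").rate == pytest.approx(0.0, abs=1e-20)

    def test_missing_metabolite_rejected(self):
        with pytest.raises(bs.InvalidInputError):
            bs.specific_metabolite_rate(make_series([0, 48]), "glucose")

    def test_round_trip_with_generating_closed_form(self):
        fit = bs.GrowthFit(mu=0.028, initial_density=1e5, r_squared=1.0)
        times = np.array([0.0, 72.0, 120.0, 168.0])
        events = (
            bs.ExchangeEvent(time=24.0, fraction=0.5, fresh={"glucose": 2.0}),
            bs.ExchangeEvent(time=120.0, fraction=0.5, fresh={"glucose": 2.0}),
        )
        q_true = 3.0e-12
        conc = bs.predict_metabolite_profile(
            fit, q_true, 2.0, times, direction="consumption",
            exchange_events=events, metabolite="glucose",
        )
        series = bs.CultureTimeSeries(
            times=times,
            viable_density=bs.predict_density(fit, times),
            metabolites={"glucose": conc},
            exchange_events=events,
        )
        rates = bs.specific_metabolite_rate(series, "glucose")
        assert rates.rate == pytest.approx(q_true, rel=0.01)
        assert rates.r_squared > 0.999


class TestMetabolitePrediction:
    def test_initial_value(self):
        fit = bs.GrowthFit(mu=0.028, initial_density=1e5, r_squared=1.0)
        assert bs.predict_metabolite_profile(fit, 3e-12, 2.0, [0.0])[0] == pytest.approx(2.0)

    def test_zero_growth_limit_matches_linear_form(self):
        cx0, q, c0 = 1e5, 3e-12, 2.0
        tiny = bs.GrowthFit(mu=1e-12, initial_density=cx0, r_squared=1.0)
        t = np.array([0.0, 50.0, 150.0])
        got = bs.predict_metabolite_profile(tiny, q, c0, t, direction="consumption")
        linear = c0 - q * cx0 * ML_PER_L * t
        assert np.allclose(got, linear, rtol=1e-6)

    def test_depletion_clamped_with_warning(self):
        fit = bs.GrowthFit(mu=0.05, initial_density=1e6, r_squared=1.0)
        with pytest.warns(RuntimeWarning):
            out = bs.predict_metabolite_profile(fit, 1e-10, 0.5, [0.0, 168.0])
        assert out[-1] == 0.0

    def test_mutually_inverse_with_rate_estimator(self):
        # noiseless forward-backward error well under 1e-6 relative
        fit = bs.GrowthFit(mu=0.02, initial_density=2e5, r_squared=1.0)
        times = np.linspace(0, 168, 8)
        conc = bs.predict_metabolite_profile(fit, 4e-12, 2.0, times, direction="consumption")
        series = bs.CultureTimeSeries(
            times=times,
            viable_density=bs.predict_density(fit, times),
            metabolites={"glucose": conc},
        )
        rates = bs.specific_metabolite_rate(series, "glucose")
        assert rates.rate == pytest.approx(4e-12, rel=1e-6)


class TestLactateGlucoseRatio:
    def test_direct_arithmetic(self):
        series = make_series(
            [0, 96],
            metabolites={
                "glucose": np.array([2.0, 1.0]),
                "lactate": np.array([0.0, 0.9]),
            },
        )
        assert bs.lactate_glucose_ratio(series) == pytest.approx(0.9)

    def test_no_lactate_production(self):
        series = make_series(
            [0, 96],
            metabolites={"glucose": np.array([2.0, 1.0]), "lactate": np.array([0.2, 0.2])},
        )
        assert bs.lactate_glucose_ratio(series) == pytest.approx(0.0)

    def test_zero_consumption_rejected(self):
        series = make_series(
            [0, 96],
            metabolites={"glucose": np.array([2.0, 2.0]), "lactate": np.array([0.0, 0.5])},
        )
        with pytest.raises(bs.UndefinedStatisticError):
            bs.lactate_glucose_ratio(series)

    def test_invariant_to_neutral_exchange(self):
        times = [0, 60, 120]
        mets = {
            "glucose": np.array([2.0, 1.4, 0.9]),
            "lactate": np.array([0.0, 0.5, 0.9]),
        }
        plain = make_series(times, metabolites=mets)
        ev = bs.ExchangeEvent(
            time=60.0, fraction=0.5, fresh={"glucose": 1.4, "lactate": 0.5}
        )
        with_ev = make_series(times, metabolites=mets, events=[ev])
        assert bs.lactate_glucose_ratio(with_ev) == pytest.approx(
            bs.lactate_glucose_ratio(plain), rel=1e-12
        )
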