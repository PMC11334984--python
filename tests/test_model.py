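import numpy as np
import pytest

from vocalturns.corpus import CallRecord, Session
from vocalturns.model import (
    ArousalCurve,
    CorrectionModel,
    FactorSet,
    InterruptionCurve,
    RampModel,
    ResponseCurve,
    SimConfig,
    TurnTakingModel,
    fit_arousal,
    fit_correction_model,
    fit_interruption_curve,
    fit_response_curves,
    fit_state_model,
    interpolate_state_trace,
    simulate_response_delay_ramp,
    simulate_session,
)
from vocalturns.synth import (
    gen_model_corpus,
    gen_poisson_corpus,
    gen_state_corpus,
)


def constant_rate_corpus(per_window=6, n_sessions=3):
    corpus = []
    for k in range(n_sessions):
        calls = [CallRecord(f"c{k}", "M1", t, t + 1.0)
                 for t in np.arange(0, 1800, 30.0 / (per_window / 6))]
        corpus.append(Session(f"c{k}", 1800, "solo", ["M1"], calls))
    return corpus


class TestStateModel:
    def test_constant_rate_fixed_point(self):
        sm = fit_state_model(constant_rate_corpus())
        assert sm.residual_sd == pytest.approx(0.0, abs=1e-8)
        x = np.full(5, 6.0)
        pred = sm.intercept + x @ sm.coefficients
        assert pred == pytest.approx(6.0, abs=1e-6)

    def test_training_pairs_per_series(self):
        # a 55-window series yields 50 (5-lag -> next) pairs
        corpus = constant_rate_corpus(n_sessions=1)
        from vocalturns.corpus import rolling_rate

        series = rolling_rate(corpus[0], "M1")
        assert len(series) == 55
        assert len(series) - 5 == 50

    def test_ar5_coefficients_recovered(self):
        truth = np.array([0.05, 0.05, 0.1, 0.2, 0.4])
        corpus = gen_state_corpus(coefs=truth, n_sessions=40, seed=5)
        sm = fit_state_model(corpus)
        for i in range(5):
            in_ci = sm.conf_int[i][0] <= truth[i] <= sm.conf_int[i][1]
            close = abs(sm.coefficients[i] - truth[i]) <= 0.1 * truth[i]
            assert in_ci or close

    def test_generated_bank_normalized(self):
        corpus = gen_state_corpus(n_sessions=5, seed=1)
        sm = fit_state_model(corpus)
        bank = sm.generate_bank(np.random.default_rng(0))
        assert bank.shape == (200, 70)
        np.testing.assert_allclose(bank.mean(axis=1), 1.0, atol=1e-9)
        assert np.all(bank > 0)

    def test_zero_noise_constant_trace(self):
        from vocalturns.model import StateModel

        sm = StateModel(coefficients=np.full(5, 0.2), intercept=0.0,
                        residual_sd=0.0, rate_mean=5.0, rate_sd=0.0)
        bank = sm.generate_bank(np.random.default_rng(0))
        np.testing.assert_allclose(bank, 1.0)

    def test_trace_autocorrelation_matches_process(self):
        """Generated traces inherit the AR process's short-lag
        autocorrelation (compared distributionally against direct
        realizations of the same recursion)."""
        corpus = gen_state_corpus(n_sessions=20, seed=3)
        sm = fit_state_model(corpus)
        bank = sm.generate_bank(np.random.default_rng(1))

        def lag1(x):
            return np.corrcoef(x[:-1], x[1:])[0, 1]

        gen_ac = np.array([lag1(t) for t in bank])
        rng = np.random.default_rng(2)
        direct = []
        for _ in range(100):
            v = np.full(5, sm.rate_mean)
            vals = []
            for _ in range(140):
                nxt = sm.intercept + v @ sm.coefficients \
                    + rng.normal(0, sm.residual_sd)
                v = np.append(v[1:], nxt)
                vals.append(nxt)
            direct.append(lag1(np.array(vals[70:])))
        assert abs(np.mean(gen_ac) - np.mean(direct)) < 0.15

    def test_interpolation_to_seconds(self):
        trace = np.ones(70)
        per_s = interpolate_state_trace(trace)
        assert per_s.shape == (1800,)
        np.testing.assert_allclose(per_s, 1.0)


class TestArousal:
    def test_flat_input_gives_flat_curve(self):
        corpus = constant_rate_corpus()
        ar = fit_arousal(corpus)
        t = np.arange(0, 1800)
        np.testing.assert_allclose(ar(t), 1.0, atol=0.02)

    def test_curve_mean_is_one(self):
        ar = ArousalCurve(0.8, -0.005, 0.6, -0.0003)
        t = np.arange(0, 1800)
        assert ar(t).mean() == pytest.approx(1.0, abs=1e-3)

    def test_known_decay_recovered(self):
        truth = ArousalCurve(0.8, -0.005, 0.6, -0.0003)
        corpus = gen_poisson_corpus([200, 200], n_sessions=100, seed=4,
                                    rate_profile=truth)
        fitted = fit_arousal(corpus)
        t = np.arange(0, 1800)
        # the two-term exponential is only identified as a curve (amplitude
        # and rate pairs trade off); recovery is asserted pointwise
        rel = np.abs(fitted(t) - truth(t)) / truth(t)
        assert rel.max() < 0.1


class TestInterruptionCurve:
    def test_25_bins(self):
        ic = InterruptionCurve(decay_rate=1.5)
        assert len(ic.values()) == 25
        assert ic.values()[0] == 1.0
        assert np.all(np.diff(ic.values()) <= 0)

    def test_no_overlaps_degenerate_path(self):
        calls = [CallRecord("s", "M1", 0.0, 1.0),
                 CallRecord("s", "M2", 100.0, 101.0)]
        corpus = [Session("s", 1800, "pair", ["M1", "M2"], calls)]
        ic = fit_interruption_curve(corpus)
        assert ic.degenerate
        v = ic.values()
        assert v[0] == 1.0 and np.all(v[1:] == 0)

    def test_known_decay_recovered(self):
        f = FactorSet.identity()
        f.interruption = InterruptionCurve(decay_rate=1.5)
        corpus = gen_model_corpus(f, rates=(100, 100), n_sessions=60, seed=1)
        ic = fit_interruption_curve(corpus)
        assert ic.decay_rate == pytest.approx(1.5, rel=0.15)


class TestResponseCurves:
    def test_poisson_partner_curve_flat(self):
        corpus = gen_poisson_corpus([80, 80], n_sessions=40, seed=2)
        rs, rp = fit_response_curves(corpus)
        assert np.abs(rp.values[5:] - 1.0).max() < 0.25

    def test_base_window_normalized(self, truth_corpus):
        rs, rp = fit_response_curves(truth_corpus)
        assert rs.values[-10:].mean() == pytest.approx(1.0, abs=0.01)
        assert rp.values[-10:].mean() == pytest.approx(1.0, abs=0.01)

    def test_planted_refractory_and_peak_recovered(self, truth_factors):
        corpus = gen_model_corpus(truth_factors, rates=(80, 80),
                                  n_sessions=40, seed=3)
        rs, rp = fit_response_curves(corpus)
        # refractory: mean of the first 2 s below baseline
        assert rs.values[:2].mean() < 1.0
        # rebound peak within 1 s of the planted 3 s position
        assert abs(np.argmax(rs.values) + 0.5 - 3.0) <= 1.0
        assert abs(np.argmax(rp.values) + 0.5 - 3.0) <= 1.0


class TestCorrection:
    def test_zero_discrepancy_is_identity(self):
        cm = CorrectionModel(0.0, 0.0, 0.0)
        np.testing.assert_allclose(cm.corrected_inputs(np.array([50.0, 80.0])),
                                   [50.0, 80.0])

    def test_monotone_in_observed_output(self):
        cm = CorrectionModel(0.01, 3e-4, 5e-4)
        lo = cm.inferred_inputs(np.array([40.0, 60.0]))
        hi = cm.inferred_inputs(np.array([80.0, 60.0]))
        assert hi[0] > lo[0]

    def test_identity_factors_give_near_zero_discrepancy(self):
        cm = fit_correction_model(FactorSet.identity(), n_reps=1, seed=0)
        grid = np.arange(10.0, 301.0, 50.0)
        rel = cm.relative_discrepancy(grid, grid[::-1])
        assert np.abs(rel).max() < 0.05


class TestSimulateSession:
    def test_zero_rate_no_calls(self):
        s = simulate_session(SimConfig(rates=(0.0, 0.0)), seed=0)
        assert len(s.calls) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(rates=(-5.0, 10.0))

    def test_identity_conservation(self):
        counts = []
        for seed in range(50):
            s = simulate_session(SimConfig(rates=(60.0, 60.0)), seed=seed)
            counts.append(len(s.calls) / 2)
        counts = np.array(counts)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 60.0) <= 3 * se

    def test_caller_never_overlaps_itself(self, truth_factors):
        s = simulate_session(SimConfig(rates=(200.0, 200.0)),
                             truth_factors, seed=1)
        for cid in s.roster:
            own = s.calls_by(cid)
            for a, b in zip(own[:-1], own[1:]):
                assert b.onset >= a.offset

    def test_suppression_zero_identical_to_base(self, truth_factors):
        cfg0 = SimConfig(rates=(60.0, 60.0, 60.0), suppression=0.0)
        a = simulate_session(cfg0, truth_factors, seed=5)
        b = simulate_session(cfg0, truth_factors, seed=5)
        np.testing.assert_array_equal(a.onsets(), b.onsets())

    def test_self_refractory_and_partner_peak_expressed(self, truth_factors,
                                                        truth_corpus):
        """Simulated output shows suppressed self-calling shortly after a
        call's offset and elevated partner calling near the planted peak."""
        rs, rp = fit_response_curves(truth_corpus)
        assert rs.values[:2].mean() < rs.values[2:5].mean()
        assert rp.values.max() > 1.2


class TestRamp:
    def test_zero_noise_exact_delay(self):
        m = RampModel(base=0.5, drift=0.5, noise_sd=0.0, threshold=3.0)
        d = simulate_response_delay_ramp(m, n_epochs=10, seed=0)
        np.testing.assert_allclose(d, (3.0 - 0.5) / 0.5)

    def test_mean_delay_decreasing_in_base(self):
        means = []
        for base in (0.0, 0.5, 1.0, 1.5, 2.0):
            m = RampModel(base=base, drift=1.0, noise_sd=0.5, threshold=3.0)
            d = simulate_response_delay_ramp(m, n_epochs=2000, seed=1)
            means.append(np.nanmean(d))
        assert np.all(np.diff(means) < 0)

    def test_deterministic(self):
        m = RampModel(noise_sd=0.4)
        a = simulate_response_delay_ramp(m, n_epochs=100, seed=3)
        b = simulate_response_delay_ramp(m, n_epochs=100, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RampModel(base=3.0, threshold=2.0)
        with pytest.raises(ValueError):
            RampModel(drift=0.0)


class TestFactorSet:
    def test_unknown_ablation_errors(self, truth_factors):
        with pytest.raises(ValueError):
            truth_factors.ablate("volume")

    def test_json_round_trip(self, truth_factors):
        import dataclasses

        f = dataclasses.replace(truth_factors,
                                correction=CorrectionModel(0.01, 2e-4, 3e-4))
        back = FactorSet.from_json(f.to_json())
        np.testing.assert_allclose(back.state.coefficients,
                                   f.state.coefficients)
        np.testing.assert_allclose(back.response_self.values,
                                   f.response_self.values)
        assert back.correction.coef_own == f.correction.coef_own
        assert back.arousal.b == f.arousal.b
        # simulation from the round-tripped factors is identical
        a = simulate_session(SimConfig(rates=(60, 60)), f, seed=9)
        b = simulate_session(SimConfig(rates=(60, 60)), back, seed=9)
        np.testing.assert_array_equal(a.onsets(), b.onsets())

    def test_negative_response_curve_rejected(self):
        with pytest.raises(ValueError):
            ResponseCurve(np.array([-0.1] + [1.0] * 29))


class TestTurnTakingModel:
    def test_fit_produces_all_factors(self, truth_corpus):
        model = TurnTakingModel(calibrate=False).fit(truth_corpus)
        f = model.factors
        assert f.state is not None and f.arousal is not None
        assert f.interruption is not None
        assert f.response_self is not None and f.response_partner is not None
        assert 1.0 < f.call_length_mean < 4.0

    def test_unfitted_simulate_errors(self):
        with pytest.raises(ValueError):
            TurnTakingModel().simulate((60, 60))
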