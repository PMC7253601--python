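"""Sensorgram preprocessing and 1:1 kinetic parameter estimation."""

import numpy as np
import pytest

import coperon as cp
from coperon.kinetics import (
    InvalidInputError,
    NoBindingSignalError,
    PHASES,
)

NOISELESS = cp.NoiseModel.noiseless()


def make_trace(segments, conc=125e-9, sensor_id="s"):
    """Build a sensorgram from {phase: response array} at 1 s sampling."""
    phases, ys = zip(*[(p, np.asarray(y, dtype=float)) for p, y in segments])
    y = np.concatenate(ys)
    t = np.arange(y.size, dtype=float)
    labels = np.concatenate([np.full(v.size, p, dtype=object) for p, v in zip(phases, ys)])
    return cp.Sensorgram(time=t, response=y, phase=labels,
                         analyte_conc=conc, sensor_id=sensor_id)


class TestReferenceBaseline:
    def test_shared_constant_baseline_zeroed(self, wt_params):
        sset = cp.simulate_set(wt_params, noise=NOISELESS, seed=0)
        out = cp.subtract_reference_baseline(sset)
        for s in out:
            _, y = s.segment("secondary_baseline")
            np.testing.assert_allclose(y, 0.0, atol=1e-9)

    def test_single_sensor_baseline_becomes_zero_mean(self, wt_params):
        g = cp.simulate_sensorgram(wt_params, 125e-9, noise=cp.NoiseModel(0.01, 0, 0),
                                   seed=1)
        out = cp.subtract_reference_baseline(cp.SensorgramSet([g]))
        _, y = out.sensorgrams[0].segment("secondary_baseline")
        assert abs(y.mean()) < 1e-12

    def test_common_mode_drift_removed(self, wt_params):
        drift = cp.NoiseModel(0.0, 0.0, 2e-3)
        noisy = cp.simulate_set(wt_params, noise=drift, seed=0)
        clean = cp.simulate_set(wt_params, noise=NOISELESS, seed=0)
        out = cp.subtract_reference_baseline(noisy)
        ref = cp.subtract_reference_baseline(clean)
        for a, b in zip(out, ref):
            np.testing.assert_allclose(a.response, b.response, atol=1e-9)

    def test_missing_secondary_baseline_names_sensor(self):
        g = make_trace([("association", np.ones(20)), ("dissociation", np.ones(20))],
                       sensor_id="odd_one")
        with pytest.raises(InvalidInputError, match="odd_one"):
            cp.subtract_reference_baseline(cp.SensorgramSet([g]))


class TestSavgol:
    def test_constant_trace_unchanged(self):
        g = make_trace([("association", np.full(50, 3.5))])
        out = cp.smooth_savgol(g)
        np.testing.assert_allclose(out.response, 3.5, atol=1e-12)

    def test_reproduces_polynomials_up_to_order(self):
        t = np.arange(60, dtype=float)
        for deg in (1, 2, 3):
            y = np.polyval(np.arange(deg + 1) + 1.0, t / 60)
            g = make_trace([("association", y)])
            out = cp.smooth_savgol(g, window=11, polyorder=3)
            np.testing.assert_allclose(out.response, y, atol=1e-9)

    def test_noise_reduced_against_truth(self, wt_params):
        clean = cp.simulate_sensorgram(wt_params, 250e-9, noise=NOISELESS, seed=2)
        noisy = cp.simulate_sensorgram(wt_params, 250e-9,
                                       noise=cp.NoiseModel(0.02, 0, 0), seed=2)
        smoothed = cp.smooth_savgol(noisy)
        before = np.std(noisy.response - clean.response)
        after = np.std(smoothed.response - clean.response)
        assert after < before

    def test_short_segment_window_shrinks_with_warning(self, caplog):
        g = make_trace([("association", np.linspace(0, 1, 5)),
                        ("dissociation", np.linspace(1, 0, 50))])
        with caplog.at_level("WARNING"):
            out = cp.smooth_savgol(g, window=11, polyorder=3)
        assert "shrunk" in caplog.text
        assert out.response.size == g.response.size

    def test_invalid_window_rejected(self):
        g = make_trace([("association", np.ones(30))])
        with pytest.raises(InvalidInputError):
            cp.smooth_savgol(g, window=10)
        with pytest.raises(InvalidInputError):
            cp.smooth_savgol(g, window=3, polyorder=3)


class TestInterstepAlign:
    def test_injected_steps_removed(self, wt_params):
        steps = cp.NoiseModel(0.0, 0.05, 0.0)
        g = cp.simulate_sensorgram(wt_params, 250e-9, noise=steps, seed=3)
        aligned = cp.interstep_align(g)
        for prev, cur in zip(PHASES, PHASES[1:]):
            y_prev = aligned.response[aligned.phase == prev]
            y_cur = aligned.response[aligned.phase == cur]
            assert y_cur[0] == pytest.approx(y_prev[-1], abs=1e-12)
        clean = cp.simulate_sensorgram(wt_params, 250e-9, noise=NOISELESS, seed=3)
        # up to the tiny intrinsic sampling gaps, the aligned trace recovers
        # the step-free signal shifted to a common level
        diff = aligned.response - clean.response
        assert np.ptp(diff[aligned.phase == "association"]) < 1e-6

    def test_continuous_trace_unchanged(self):
        y = np.concatenate([np.zeros(20), np.linspace(0, 1, 30)])
        g = make_trace([("secondary_baseline", y[:20]), ("association", y[20:])])
        out = cp.interstep_align(g)
        np.testing.assert_allclose(out.response, y, atol=1e-12)

    def test_dissociation_start_equals_association_end(self, wt_params):
        g = cp.simulate_sensorgram(wt_params, 500e-9, noise=cp.NoiseModel(), seed=4)
        out = cp.interstep_align(g)
        ya = out.response[out.phase == "association"]
        yd = out.response[out.phase == "dissociation"]
        assert yd[0] == ya[-1]


class TestPreprocessConservation:
    def test_preprocessing_preserves_timestamps_and_segments(self, noisy_wt_set):
        out = cp.preprocess(noisy_wt_set)
        for before, after in zip(noisy_wt_set, out):
            np.testing.assert_array_equal(before.time, after.time)
            np.testing.assert_array_equal(before.phase, after.phase)
            assert before.sensor_id == after.sensor_id


class TestSegmentFits:
    def test_constant_dissociation_has_no_decay(self):
        g = make_trace([("dissociation", np.full(60, 2.0))])
        fit = cp.fit_dissociation(g)
        assert fit.rate <= 1e-6 and abs(fit.A) < 1e-9

    def test_noiseless_dissociation_rate_recovered(self):
        params = cp.KineticParams(k_a=1e6, k_d=0.01)
        g = cp.simulate_sensorgram(params, 500e-9, noise=NOISELESS)
        assert cp.fit_dissociation(g).rate == pytest.approx(0.01, rel=1e-4)

    def test_noisy_dissociation_rate_within_five_percent(self):
        params = cp.KineticParams(k_a=1e6, k_d=0.01)
        rates = []
        for seed in range(10):
            g = cp.simulate_sensorgram(params, 500e-9,
                                       noise=cp.NoiseModel(0.01, 0, 0), seed=seed)
            rates.append(cp.fit_dissociation(g).rate)
        assert np.mean(rates) == pytest.approx(0.01, rel=0.05)

    def test_noiseless_association_kobs(self, wt_params):
        g = cp.simulate_sensorgram(wt_params, 1000e-9, noise=NOISELESS)
        fit = cp.fit_association(g)
        assert fit.converged
        assert fit.rate == pytest.approx(1.0281, rel=1e-4)

    def test_reference_association_has_negligible_amplitude(self, wt_params):
        g = cp.simulate_sensorgram(wt_params, 0.0, noise=NOISELESS)
        fit = cp.fit_association(g)
        assert not fit.converged or abs(fit.A) < 1e-6

    def test_kobs_difference_scales_with_concentration(self, wt_params):
        g1 = cp.simulate_sensorgram(wt_params, 1000e-9, noise=NOISELESS)
        g2 = cp.simulate_sensorgram(wt_params, 500e-9, noise=NOISELESS)
        dk = cp.fit_association(g1).rate - cp.fit_association(g2).rate
        assert dk == pytest.approx(wt_params.k_a * 500e-9, rel=1e-3)


class TestRateAlgebra:
    def test_derive_ka_examples(self):
        assert cp.derive_ka(1.0281, 0.0281, 1e-6) == pytest.approx(1e6)
        assert cp.derive_ka(0.5281, 0.0281, 5e-7) == pytest.approx(1e6)
        assert cp.derive_ka(0.0281, 0.0281, 1e-6) == 0.0

    def test_derive_ka_errors(self):
        with pytest.raises(NoBindingSignalError):
            cp.derive_ka(0.01, 0.02, 1e-6)
        with pytest.raises(InvalidInputError):
            cp.derive_ka(1.0, 0.01, 0.0)

    def test_derive_equilibrium_kd(self):
        assert cp.derive_equilibrium_kd(1e6, 0.0281) == pytest.approx(28.1e-9)
        assert cp.derive_equilibrium_kd(2e6, 0.0281) == pytest.approx(14.05e-9)
        assert cp.derive_equilibrium_kd(1e6, 0.0) == 0.0
        with pytest.raises(InvalidInputError):
            cp.derive_equilibrium_kd(0.0, 0.01)


class TestGlobalFit:
    def test_noiseless_recovery_and_kd_identity(self, noiseless_wt_set, wt_params):
        fit = cp.global_fit_1to1(cp.preprocess(noiseless_wt_set))
        assert fit.converged
        assert fit.k_a == pytest.approx(wt_params.k_a, rel=1e-3)
        assert fit.k_d == pytest.approx(wt_params.k_d, rel=1e-3)
        assert fit.K_d == fit.k_d / fit.k_a
        assert fit.r_squared > 0.9999
        assert fit.n_sensors == 6
        # k_obs follows the affine law for every reported concentration
        for c, k in fit.k_obs.items():
            assert k == pytest.approx(fit.k_a * c + fit.k_d)

    def test_two_route_consistency(self, noiseless_wt_set):
        prepped = cp.preprocess(noiseless_wt_set)
        two = cp.two_stage_fit(prepped)
        glob = cp.global_fit_1to1(prepped)
        assert two.K_d == pytest.approx(glob.K_d, rel=0.01)

    def test_plateau_monotone_in_concentration(self, noiseless_wt_set):
        rises = [
            s.segment("association")[1][-1] - s.segment("association")[1][0]
            for s in sorted(noiseless_wt_set.measurement_sensors,
                            key=lambda s: s.analyte_conc)
        ]
        assert all(b >= a for a, b in zip(rises, rises[1:]))

    def test_noisy_kd_spread_below_ten_percent(self, wt_params):
        kds = []
        for seed in range(10):
            sset = cp.simulate_set(wt_params, noise=cp.NoiseModel(), seed=seed)
            kds.append(cp.global_fit_1to1(cp.preprocess(sset)).K_d)
        assert np.std(kds) < 0.1 * wt_params.K_d

    def test_requires_two_concentrations(self, wt_params):
        sset = cp.simulate_set(wt_params, concs=(250e-9,), noise=NOISELESS)
        with pytest.raises(InvalidInputError):
            cp.global_fit_1to1(sset)

    def test_reference_only_set_rejected(self, wt_params):
        ref = cp.simulate_sensorgram(wt_params, 0.0, noise=NOISELESS)
        with pytest.raises(InvalidInputError):
            cp.global_fit_1to1(cp.SensorgramSet([ref]))


class TestBindingCall:
    @staticmethod
    def _fit(kd_molar, converged=True):
        return cp.FitResult(
            k_a=1.0, k_d=kd_molar, K_d=kd_molar, k_a_se=None, k_d_se=None,
            K_d_se=None, r_max={}, k_obs={}, r_squared=0.95, n_sensors=6,
            converged=converged,
        )

    @pytest.mark.parametrize(
        "kd_nm, symbol",
        [(28.1, "++"), (164.0, "++"), (500.0, "+"), (3000.0, "+"), (5000.0, "-")],
    )
    def test_thresholds(self, kd_nm, symbol):
        assert cp.classify_binding(self._fit(kd_nm * 1e-9)).symbol == symbol

    def test_unconverged_fit_is_no_binding(self):
        assert cp.classify_binding(self._fit(10e-9, converged=False)).symbol == "-"
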