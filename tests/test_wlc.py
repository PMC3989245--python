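"""Closed-form wormlike-chain models and the Lp-extraction fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from persistlen import (CorrelationData, PhysicalContext,
                        cosine_correlation_model, fit_cosine_correlation,
                        fit_end_to_end, lp_from_mode_variance,
                        mean_square_end_to_end_model)
from persistlen.geometry import ModeAmplitudes
from persistlen.wlc import fit_modes


class TestCosineModel:
    @pytest.mark.parametrize("s, lp, amp, expected", [
        (0.0, 10.0, 1.0, 1.0),
        (20.0, 10.0, 1.0, math.exp(-1.0)),
        (6.0, 3.0, 1.0, math.exp(-1.0)),
        (5.0, 10.0, 0.97, 0.97 * math.exp(-0.25)),
    ])
    def test_values(self, s, lp, amp, expected):
        assert cosine_correlation_model(s, lp, amp) == pytest.approx(expected, rel=1e-12)

    def test_3d_convention_decays_twice_as_fast(self):
        assert cosine_correlation_model(5.0, 10.0, 1.0, convention="3d") == \
            pytest.approx(math.exp(-0.5), rel=1e-12)

    @given(lp=st.floats(0.1, 1e3), amp=st.floats(0.1, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_s(self, lp, amp):
        s = np.linspace(0.0, 10 * lp, 50)
        c = cosine_correlation_model(s, lp, amp)
        assert np.all(np.diff(c) < 0)

    def test_nonpositive_lp_rejected(self):
        with pytest.raises(ValueError):
            cosine_correlation_model(1.0, 0.0)
        with pytest.raises(ValueError):
            cosine_correlation_model(1.0, -2.0)


class TestEndToEndModel:
    def test_rigid_rod_limit(self):
        # Lp >> L: the chain is a straight rod, <R^2> -> L^2
        assert mean_square_end_to_end_model(5.0, 1e9) == pytest.approx(25.0, rel=1e-6)

    def test_formula_value(self):
        expected = 400.0 - 800.0 * (1.0 - math.exp(-0.5))  # 85.2245278...
        assert mean_square_end_to_end_model(10.0, 10.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(85.2245, abs=1e-4)

    def test_flexible_limit(self):
        # L >> Lp: <R^2> -> 4*Lp*L - 8*Lp^2
        assert mean_square_end_to_end_model(1000.0, 1.0) == pytest.approx(3992.0, rel=1e-9)

    @pytest.mark.parametrize("ratio", [1e-3, 1e3])
    def test_printed_limits_at_extreme_ratios(self, ratio):
        lp = 7.0
        L = ratio * lp
        val = mean_square_end_to_end_model(L, lp)
        if ratio < 1:
            assert val == pytest.approx(L**2, rel=1e-3)
        else:
            assert val == pytest.approx(4 * lp * L, rel=1e-2)

    @given(L=st.floats(0.01, 100.0), lp=st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_rod_and_positive(self, L, lp):
        val = mean_square_end_to_end_model(L, lp)
        assert 0.0 <= val <= L**2 * (1 + 1e-9)

    def test_matches_monte_carlo_ensemble(self):
        # independent oracle: direct vectorized tangent-walk simulation
        rng = np.random.default_rng(7)
        n, steps, lp, L = 30_000, 200, 10.0, 20.0
        ds = L / steps
        theta = np.cumsum(rng.normal(0.0, math.sqrt(ds / lp), (n, steps)), axis=1)
        theta = np.hstack([np.zeros((n, 1)), theta])[:, :-1]
        r2 = (ds * np.cos(theta).sum(axis=1)) ** 2 + (ds * np.sin(theta).sum(axis=1)) ** 2
        se = r2.std() / math.sqrt(n)
        assert abs(r2.mean() - mean_square_end_to_end_model(L, lp)) < 3 * se + 0.02 * r2.mean()


class TestModeVariance:
    def test_identity_case(self):
        assert lp_from_mode_variance(1, math.pi, 1.0) == pytest.approx(1.0, rel=1e-12)

    @given(lp=st.floats(0.1, 100.0), n=st.integers(1, 10), L=st.floats(1.0, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, lp, n, L):
        var = (L / (n * math.pi)) ** 2 / lp
        assert lp_from_mode_variance(n, L, var) == pytest.approx(lp, rel=1e-10)

    @pytest.mark.parametrize("n, L, var", [(0, 10, 1), (11, 10, 1), (1, -1, 1), (1, 10, 0)])
    def test_invalid_inputs_rejected(self, n, L, var):
        with pytest.raises(ValueError):
            lp_from_mode_variance(n, L, var)


class TestFitCosine:
    @staticmethod
    def _model_data(lp, amp, s_max=30.0, n=80, counts=1000):
        s = np.linspace(0.2, s_max, n)
        return CorrelationData(
            s_bins=s, mean_cosine=amp * np.exp(-s / (2 * lp)),
            counts=np.full(n, counts))

    def test_noiseless_round_trip(self):
        fit = fit_cosine_correlation(self._model_data(7.0, 1.0))
        assert fit.converged
        assert fit.lp == pytest.approx(7.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_explicit_fit_range_honoured(self):
        fit = fit_cosine_correlation(self._model_data(7.0, 0.9), fit_range=(0.0, 20.0))
        assert fit.fit_range == (0.0, 20.0)
        assert fit.lp == pytest.approx(7.0, rel=1e-6)

    def test_default_range_is_semiflexible_window(self):
        # automatic range stops near eight persistence lengths
        fit = fit_cosine_correlation(self._model_data(3.0, 1.0, s_max=60.0, n=200))
        assert fit.fit_range[1] == pytest.approx(8 * fit.lp, rel=0.02)

    def test_relative_angle_noise_amplitude(self):
        # straight line whose relative-angle determination carries Gaussian
        # noise: fitted amplitude must equal exp(-sigma^2/2)
        rng = np.random.default_rng(5)
        sigma, n = 0.25, 20_000
        s = np.arange(0.25, 10.0, 0.25)
        mc = np.array([np.cos(rng.normal(0.0, sigma, n)).mean() for _ in s])
        data = CorrelationData(s_bins=s, mean_cosine=mc, counts=np.full(len(s), n))
        fit = fit_cosine_correlation(data, fit_range=(0.0, 10.0))
        assert fit.converged
        assert fit.amplitude == pytest.approx(math.exp(-sigma**2 / 2), abs=0.005)

    def test_angle_noise_depresses_amplitude_below_one(self):
        from persistlen import compute_cosine_correlation, simulate_wlc_2d
        from persistlen.synthetic import WLCParams

        shapes = simulate_wlc_2d(WLCParams(lp=10.0, contour_length=30.0,
                                           seed=41, n_chains=200))
        noise = np.random.default_rng(42)
        for sh in shapes:
            sh.tangent_angles = sh.tangent_angles + noise.normal(
                0.0, 0.25, len(sh.tangent_angles))
        fit = fit_cosine_correlation(compute_cosine_correlation(shapes, bin_width=0.5))
        assert fit.converged
        assert fit.amplitude < 1.0
        assert fit.lp == pytest.approx(10.0, rel=0.15)

    def test_too_few_bins_is_explicit_failure(self):
        data = self._model_data(7.0, 1.0)
        fit = fit_cosine_correlation(data, fit_range=(100.0, 200.0))
        assert not fit.converged
        assert math.isnan(fit.lp)
        assert "bins" in fit.message

    def test_flexural_rigidity_reported(self):
        ctx = PhysicalContext(temperature=298.15)
        fit = fit_cosine_correlation(self._model_data(10.0, 1.0), context=ctx)
        # kappa = Lp * kT with Lp in metres
        assert fit.flexural_rigidity == pytest.approx(10e-6 * ctx.kT, rel=1e-5)


class TestFitEndToEnd:
    @staticmethod
    def _records_on_curve(lp, lengths):
        return [(L, float(mean_square_end_to_end_model(L, lp))) for L in lengths]

    def test_round_trip(self):
        recs = self._records_on_curve(4.0, np.linspace(2.0, 40.0, 25))
        fit = fit_end_to_end(recs, n_bins=25)
        assert fit.converged
        assert fit.lp == pytest.approx(4.0, rel=1e-6)

    def test_requires_ten_records(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_end_to_end(self._records_on_curve(4.0, np.linspace(2, 20, 9)))

    def test_geometrically_impossible_records_rejected(self):
        recs = self._records_on_curve(4.0, np.linspace(2.0, 20.0, 12))
        recs[3] = (recs[3][0], recs[3][0] ** 2 * 1.5)  # R^2 > L^2
        with pytest.raises(ValueError, match="impossible"):
            fit_end_to_end(recs)

    def test_identical_lengths_rejected(self):
        recs = [(5.0, 20.0)] * 12
        with pytest.raises(ValueError, match="same contour length"):
            fit_end_to_end(recs)


class TestFitModes:
    def test_recovers_lp_from_equipartition_draws(self):
        rng = np.random.default_rng(9)
        lp, L, n_frames = 12.0, 18.0, 4000
        modes = list(range(1, 11))
        sd = np.array([math.sqrt((L / (n * math.pi)) ** 2 / lp) for n in modes])
        amps = rng.normal(0.0, 1.0, (n_frames, len(modes))) * sd
        ma = ModeAmplitudes(mode_numbers=modes, amplitudes=amps,
                            filament_length=L, n_frames=n_frames)
        fit = fit_modes(ma)
        assert fit.method == "modes"
        assert fit.lp == pytest.approx(lp, rel=0.1)
        for n, lp_n in fit.per_mode_lp.items():
            assert lp_n == pytest.approx(lp, rel=0.15), f"mode {n}"

    def test_mode_subset_and_missing_mode(self):
        ma = ModeAmplitudes(mode_numbers=[1, 2], amplitudes=np.ones((3, 2)),
                            filament_length=10.0, n_frames=3)
        with pytest.raises(ValueError, match="mode 5"):
            fit_modes(ma, modes=[5])


class TestEstimatorConsistency:
    def test_three_estimators_agree_on_one_ensemble(self):
        """Cosine, end-to-end and mode estimates of the same Lp agree."""
        from persistlen import (compute_cosine_correlation,
                                compute_end_to_end_records,
                                compute_mode_amplitudes,
                                simulate_fluctuating_filament,
                                simulate_wlc_ensemble)
        from persistlen.synthetic import WLCParams

        lp_true = 10.0
        lengths = np.random.default_rng(100).uniform(5.0, 40.0, 300)
        shapes = simulate_wlc_ensemble(lp_true, lengths, seed=101)
        frames = simulate_fluctuating_filament(
            WLCParams(lp=lp_true, contour_length=15.0, seed=102), 2000)

        est = {
            "cosine": fit_cosine_correlation(compute_cosine_correlation(shapes)).lp,
            "end_to_end": fit_end_to_end(compute_end_to_end_records(shapes)).lp,
            "modes": fit_modes(compute_mode_amplitudes(frames), modes=range(1, 6)).lp,
        }
        for name, lp in est.items():
            assert lp == pytest.approx(lp_true, rel=0.15), name
        vals = list(est.values())
        assert max(vals) / min(vals) < 1.2
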