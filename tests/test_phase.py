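"""Forward-prediction phase estimator, Hilbert oracle and circular error."""

import math

import numpy as np
import pytest
from scipy.stats import circstd

from phasepower import (DEFAULT_PHASTIMATE, PhastimateParams, circular_error_sd,
                        estimate_phase_phastimate, estimate_phases_phastimate,
                        hilbert_oracle_phase, optimize_params, param_grid)

FS = 1000.0
TIMES = np.arange(-2200.0, 1001.0)
I_END = int(np.argmin(np.abs(TIMES - (-4.0))))


def _cosine(f0, phi0_deg=0.0):
    return np.cos(2 * np.pi * f0 * TIMES / 1000.0 + np.radians(phi0_deg))


class TestHilbertOracle:
    def test_cosine_peak_is_zero_degrees(self):
        # 10 Hz cosine peaks at t = 0
        assert hilbert_oracle_phase(_cosine(10.0), TIMES, "alpha", FS, 0.0) == pytest.approx(
            0.0, abs=1.0)

    def test_quarter_period_after_peak_is_90(self):
        # peak at -25 ms; a quarter of the 100 ms period later the phase is 90
        phase = hilbert_oracle_phase(_cosine(10.0), TIMES, "alpha", FS, -975.0)
        assert phase == pytest.approx(90.0, abs=1.0)

    def test_chirp_phase_advances_monotonically(self):
        f = np.linspace(8.5, 12.5, len(TIMES))
        sig = np.cos(2 * np.pi * np.cumsum(f) / 1000.0)
        phases = [hilbert_oracle_phase(sig, TIMES, "alpha", FS, t)
                  for t in np.arange(-500.0, -400.0, 5.0)]
        unwrapped = np.unwrap(np.radians(phases))
        assert np.all(np.diff(unwrapped) > 0)

    def test_edge_proximity_raises(self):
        with pytest.raises(ValueError, match="edge"):
            hilbert_oracle_phase(_cosine(10.0), TIMES, "alpha", FS, TIMES[0] + 5.0)


class TestPhastimate:
    @pytest.mark.parametrize("band", ["theta", "alpha", "beta"])
    def test_agrees_with_oracle_on_noiseless_sinusoids(self, band):
        """Convention coherence: forecast and oracle agree within 10 degrees
        circular SD over random in-band sinusoids."""
        from phasepower import get_band
        b = get_band(band)
        params = DEFAULT_PHASTIMATE[band]
        rng = np.random.default_rng(42)
        est, ref = [], []
        for _ in range(100):
            f0 = rng.uniform(b.lo + 0.5, b.hi - 0.5)
            sig = _cosine(f0, rng.uniform(0, 360))
            e = estimate_phase_phastimate(sig[:I_END + 1], params, band, FS, -4.0, 0.0)
            est.append(e.phase_deg)
            ref.append(hilbert_oracle_phase(sig, TIMES, band, FS, 0.0))
        assert math.degrees(circular_error_sd(np.array(est), np.array(ref))) < 10.0

    def test_cosine_peak_and_trough(self):
        params = DEFAULT_PHASTIMATE["alpha"]
        peak = estimate_phase_phastimate(_cosine(10.0)[:I_END + 1], params, "alpha", FS, -4.0, 0.0)
        err = (peak.phase_deg + 180.0) % 360.0 - 180.0
        assert abs(err) < 5.0
        trough = estimate_phase_phastimate(_cosine(10.0, 180.0)[:I_END + 1], params,
                                           "alpha", FS, -4.0, 0.0)
        assert abs(trough.phase_deg - 180.0) < 5.0

    def test_white_noise_error_larger_than_high_snr(self):
        params = DEFAULT_PHASTIMATE["alpha"]
        rng = np.random.default_rng(11)
        n_trials = 60
        f0 = rng.uniform(8.5, 12.5, n_trials)
        phi = rng.uniform(0, 360, n_trials)
        osc = np.cos(2 * np.pi * f0[None, :] * TIMES[:, None] / 1000.0 + np.radians(phi)[None, :])
        noise = rng.standard_normal((len(TIMES), n_trials))
        errors = {}
        for label, sig in (("noise", noise), ("snr10", 10 * osc + noise)):
            est = estimate_phases_phastimate(sig[:I_END + 1], params, "alpha", FS, -4.0, 0.0)
            ref = hilbert_oracle_phase(sig, TIMES, "alpha", FS, 0.0)
            ok = np.isfinite(est)
            errors[label] = circular_error_sd(est[ok], ref[ok])
        assert errors["noise"] > errors["snr10"]

    def test_short_window_raises(self):
        params = DEFAULT_PHASTIMATE["alpha"]
        with pytest.raises(ValueError, match="samples"):
            estimate_phase_phastimate(np.zeros(100), params, "alpha", FS)

    def test_output_wrapped(self):
        rng = np.random.default_rng(12)
        sig = rng.standard_normal(I_END + 1)
        est = estimate_phase_phastimate(sig, DEFAULT_PHASTIMATE["beta"], "beta", FS, -4.0, 0.0)
        assert 0.0 <= est.phase_deg < 360.0


class TestCircularErrorSD:
    def test_identical_angles_zero(self):
        a = np.array([10.0, 250.0, 359.0])
        assert circular_error_sd(a, a) == 0.0

    def test_known_two_point_dispersion(self):
        # differences {0, 90}: R = |(1 + i)/2| = sqrt(2)/2
        sd = circular_error_sd(np.array([0.0, 90.0]), np.array([0.0, 0.0]))
        assert sd == pytest.approx(math.sqrt(-2 * math.log(math.sqrt(2) / 2)), rel=1e-12)
        assert sd == pytest.approx(0.8326, abs=1e-4)

    def test_uniform_four_point_dispersion_infinite(self):
        sd = circular_error_sd(np.array([0.0, 90.0, 180.0, 270.0]), np.zeros(4))
        assert math.isinf(sd)

    def test_matches_scipy_circstd(self):
        rng = np.random.default_rng(13)
        est = rng.uniform(0, 360, 50)
        ref = est + rng.normal(0, 20, 50)
        diff = np.radians((est - ref + 180.0) % 360.0 - 180.0)
        assert circular_error_sd(est, ref) == pytest.approx(circstd(diff), rel=1e-9)

    def test_wrap_invariance(self):
        est = np.array([350.0, 10.0])
        ref = np.array([10.0, 350.0])
        # differences wrap to -20 and +20, symmetric dispersion
        assert circular_error_sd(est, ref) == pytest.approx(
            circular_error_sd(est + 360.0, ref), rel=1e-12)


class TestOptimizeParams:
    def _training(self, seed=14, n_trials=25):
        rng = np.random.default_rng(seed)
        f0 = rng.uniform(8.5, 12.5, n_trials)
        phi = rng.uniform(0, 360, n_trials)
        osc = np.cos(2 * np.pi * f0[None, :] * TIMES[:, None] / 1000.0 + np.radians(phi)[None, :])
        return 5 * osc + 0.5 * rng.standard_normal((len(TIMES), n_trials))

    def test_singleton_grid_returned(self):
        sig = self._training()
        row = DEFAULT_PHASTIMATE["alpha"]
        assert optimize_params(sig, TIMES, "alpha", FS, [row]) == row

    def test_good_beats_degenerate(self):
        sig = self._training()
        good = DEFAULT_PHASTIMATE["alpha"]
        degenerate = PhastimateParams(good.filter_order, good.window_size_ms,
                                      good.edge_ms, 1, good.hilbert_window)
        assert optimize_params(sig, TIMES, "alpha", FS, [degenerate, good]) == good

    def test_deterministic_selection(self):
        sig = self._training()
        grid = param_grid([192], [718.0], [65.0], [10, 25], [128])
        first = optimize_params(sig, TIMES, "alpha", FS, grid)
        second = optimize_params(sig, TIMES, "alpha", FS, grid)
        assert first == second

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="empty"):
            optimize_params(self._training(), TIMES, "alpha", FS, [])
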