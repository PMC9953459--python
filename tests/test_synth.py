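"""Synthetic-EEG generator: determinism, ground truth, continuation structure."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.signal import hilbert

from phasepower import (BandSpec, EvokedKernel, GenConfig, generate_dataset, get_band,
                        truth_phase, welch_band_power)
from phasepower.preprocess import PreprocConfig, preprocess


def small_cfg(**kw):
    defaults = dict(n_datasets=1, n_trials=30, seed=5)
    defaults.update(kw)
    return GenConfig(**defaults)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = small_cfg()
        a = generate_dataset(cfg, 0)
        b = generate_dataset(cfg, 0)
        assert np.array_equal(a.data, b.data)
        assert a.truth.table.equals(b.truth.table)

    def test_different_dataset_index_independent(self):
        cfg = small_cfg()
        a = generate_dataset(cfg, 0)
        b = generate_dataset(cfg, 1)
        assert not np.allclose(a.data, b.data)


class TestConfigValidation:
    def test_artifact_must_be_inside_epoch(self):
        with pytest.raises(ValueError, match="artifact_span"):
            small_cfg(epoch_span=(-1.0, 1000.0))

    def test_response_window_must_be_inside_epoch(self):
        with pytest.raises(ValueError, match="response window"):
            small_cfg(epoch_span=(-2200.0, 60.0), artifact_span=(-2.0, 20.0))

    def test_illposed_gains_rejected(self):
        # worst case 1 + gamma*z + kappa*cos(phi) < 0 over |z| <= 1.5
        with pytest.raises(ValueError, match="negative"):
            small_cfg(gain_power_interaction=0.5, gain_phase_interaction=0.6)

    def test_boundary_gain_accepted(self):
        cfg = small_cfg(gain_power_interaction=0.6, gain_phase_interaction=0.1)
        es = generate_dataset(cfg, 0)
        assert np.all(es.truth.table["evoked_gain"] >= 0)


class TestEvokedKernel:
    def test_waveform_peaks_in_response_window_and_decays(self):
        t = np.arange(0.0, 1000.0)
        k = EvokedKernel(peak_uv=5.0).waveform(t)
        assert np.max(np.abs(k)) == pytest.approx(5.0)
        t_peak = t[np.argmax(np.abs(k))]
        assert 25.0 <= t_peak <= 80.0
        assert np.max(np.abs(k[t >= 150.0])) < 0.25  # died out by ~150 ms

    def test_twin_datasets_differ_exactly_by_kernel(self):
        """Same seed with and without the kernel: the difference is the
        injected response (gain 1 under null gains), outside the artifact."""
        cfg_on = small_cfg(evoked_kernel=EvokedKernel(peak_uv=10.0))
        cfg_off = small_cfg(evoked_kernel=EvokedKernel(peak_uv=0.0))
        on = generate_dataset(cfg_on, 0)
        off = generate_dataset(cfg_off, 0)
        sel = on.times > 20.0
        expected = EvokedKernel(peak_uv=10.0).waveform(on.times[sel])
        diff = on.data[sel, :] - off.data[sel, :]
        assert np.allclose(diff, expected[:, None], atol=1e-9)
        assert np.allclose(on.data[on.times < 0.0], off.data[off.times < 0.0])

    def test_power_interaction_scales_kernel_with_z(self):
        cfg = small_cfg(gain_power_interaction=0.5, n_trials=50)
        es = generate_dataset(cfg, 0)
        t = es.truth.table
        assert np.allclose(t["evoked_gain"], 1.0 + 0.5 * t["z_power_alpha"])


class TestTruthPhase:
    def test_matches_independent_hilbert_of_clean_trace(self):
        cfg = small_cfg()
        es = generate_dataset(cfg, 0)
        clean = es.truth.clean["alpha"].real
        i = es.time_index(0.0)
        oracle = np.degrees(np.angle(hilbert(clean, axis=0)[i, :])) % 360.0
        got = truth_phase(es, "alpha", 0.0)
        err = (got - oracle + 180.0) % 360.0 - 180.0
        assert np.max(np.abs(err)) < 1.0

    def test_peak_and_quarter_period_convention(self):
        # a one-DFT-bin band at exactly 10 Hz is a pure sinusoid per trial
        narrow = BandSpec("osc", 9.9, 10.1, 500.0)
        cfg = small_cfg(band_amplitudes={"osc": 5.0}, band_specs={"osc": narrow},
                        interaction_band="osc", noise_scale=0.0,
                        evoked_kernel=EvokedKernel(peak_uv=0.0), artifact_amplitude=0.0)
        es = generate_dataset(cfg, 0)
        phases0 = truth_phase(es, "osc", 0.0)
        # find, per trial, the sample where the clean trace peaks near t=0
        clean = es.truth.clean["osc"]
        for j in range(5):
            seg = clean[:, j].real
            i0 = es.time_index(0.0)
            local = slice(i0 - 60, i0 + 60)
            i_peak = np.argmax(seg[local]) + i0 - 60
            t_peak = es.times[i_peak]
            p_at_peak = truth_phase(es, "osc", t_peak)[j]
            assert min(p_at_peak, 360.0 - p_at_peak) < 5.0
            p_quarter = truth_phase(es, "osc", t_peak + 25.0)[j]  # quarter of 100 ms
            assert p_quarter == pytest.approx(90.0, abs=5.0)

    def test_missing_truth_raises(self):
        cfg = small_cfg()
        es = generate_dataset(cfg, 0)
        es.truth = None
        with pytest.raises(ValueError, match="ground-truth"):
            truth_phase(es, "alpha", 0.0)


class TestContinuation:
    def test_prestimulus_band_power_predicts_post_window_amplitude(self):
        """Per-epoch amplitude persistence: the trial's band power predicts
        the post-window (25-80 ms) mean square of the ongoing oscillation."""
        cfg = small_cfg(n_trials=600, evoked_kernel=EvokedKernel(peak_uv=0.0), seed=11)
        es = generate_dataset(cfg, 0)
        m = (es.times >= 25.0) & (es.times <= 80.0)
        for name in ("theta", "alpha", "beta"):
            band_power = (cfg.band_amplitudes[name]
                          * es.truth.table[f"amp_mult_{name}"].to_numpy()) ** 2
            post_ms = (es.truth.clean[name][m, :].real ** 2).mean(axis=0)
            r = np.corrcoef(band_power, post_ms)[0, 1]
            assert r > 0.5, f"{name}: continuation correlation {r:.2f}"

    def test_measured_welch_power_correlates_positively(self):
        cfg = small_cfg(n_trials=800, evoked_kernel=EvokedKernel(peak_uv=0.0), seed=12)
        es = generate_dataset(cfg, 0)
        clean = es.truth.clean
        es = preprocess(es, PreprocConfig())
        m = (es.times >= 25.0) & (es.times <= 80.0)
        for name in ("theta", "alpha", "beta"):
            band = get_band(name)
            _, pw = es.window(-band.power_window_ms, 0.0)
            p = welch_band_power(pw, band, es.fs)
            post_ms = (clean[name][: len(es.times)][m, :].real ** 2).mean(axis=0)
            # measured power carries short-window estimation noise, so the
            # correlation is attenuated relative to the truth-level one
            assert np.corrcoef(p, post_ms)[0, 1] > 0.1


class TestNullStationarity:
    def test_post_window_matches_control_window_without_kernel(self):
        """With no evoked response and null gains, the post-stimulus window
        has the same marginal power as the pre-stimulus control window."""
        cfg = small_cfg(n_trials=500, evoked_kernel=EvokedKernel(peak_uv=0.0), seed=19)
        es = generate_dataset(cfg, 0)
        post = es.window(25.0, 80.0)[1]
        ctl = es.window(-971.0, -916.0)[1]
        ratio = (post**2).mean() / (ctl**2).mean()
        assert ratio == pytest.approx(1.0, abs=0.1)


class TestEpochSetContract:
    def test_no_nans_and_uniform_times(self):
        es = generate_dataset(small_cfg(), 0)
        assert np.all(np.isfinite(es.data))
        assert np.allclose(np.diff(es.times), 1.0)

    def test_roundtrip_save_load(self, tmp_path):
        es = generate_dataset(small_cfg(n_trials=5), 0)
        es.save(tmp_path / "ds")
        back = type(es).load(tmp_path / "ds")
        assert np.allclose(back.data, es.data, atol=1e-6)
        assert back.fs == es.fs
        assert len(back.truth.table) == 5
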