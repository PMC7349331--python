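"""Time-series synthesis, noise injection, and corpus assembly."""

from dataclasses import replace

import numpy as np
import pytest

import dlsann.simulate as sim
from dlsann import (
    NoiseConfig,
    SynthesisConfig,
    TimeSeries,
    add_power_grid_noise,
    add_random_noise,
    generate_clean_series,
    generate_clean_series_direct,
    generate_noisy_series,
    generate_training_corpus,
)
from dlsann.errors import ConfigError, DegenerateInputError, InputSizeError
from dlsann.simulate import diameter_grid


class TestCleanSynthesis:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_fast_path_matches_direct_summation(self, setup, seed):
        cfg = SynthesisConfig(diameter=500e-9, n_points=64, n_freqs=33, seed=seed)
        fast = generate_clean_series(setup, cfg)
        direct = generate_clean_series_direct(setup, cfg)
        assert np.max(np.abs(fast.samples - direct.samples)) < 1e-9

    def test_single_tone_reduces_to_pure_sine(self, setup, monkeypatch):
        # one nonzero amplitude, zero phases -> the double sum is one sine
        cfg = SynthesisConfig(diameter=1e-6, n_points=64, n_freqs=33, seed=0)
        freqs = np.arange(33) * (setup.sampling_frequency / 64)
        amps = np.zeros(33)
        amps[5] = 2.5
        phases = np.zeros(33)
        monkeypatch.setattr(
            sim, "_amplitudes_and_phases", lambda s, c: (freqs, amps, phases)
        )
        out = generate_clean_series(setup, cfg)
        t = np.arange(64) / setup.sampling_frequency
        expected = 2.5 * np.sin(2 * np.pi * freqs[5] * t)
        assert np.allclose(out.samples, expected, atol=1e-12)

    def test_deterministic_given_seed(self, setup):
        cfg = SynthesisConfig(diameter=200e-9, seed=5)
        a = generate_clean_series(setup, cfg)
        b = generate_clean_series(setup, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_inconsistent_n_freqs_rejected(self, setup):
        cfg = SynthesisConfig(diameter=1e-6, n_points=64, n_freqs=31)
        with pytest.raises(ConfigError):
            generate_clean_series(setup, cfg)

    def test_length_and_origin(self, setup):
        cfg = SynthesisConfig(diameter=1e-6, n_points=128, n_freqs=65)
        out = generate_clean_series(setup, cfg)
        assert len(out) == 128
        assert out.origin == "simulated-clean"


class TestGridNoise:
    def _series(self, setup, n=32000):
        cfg = SynthesisConfig(diameter=500e-9, n_points=n, n_freqs=n // 2 + 1, seed=3)
        return generate_clean_series(setup, cfg)

    def test_zero_coefficient_is_identity(self, setup):
        s = self._series(setup)
        out = add_power_grid_noise(s, NoiseConfig(grid_amp_coeff=0.0, seed=1))
        assert np.array_equal(out.samples, s.samples)

    def test_harmonic_count_rule(self):
        assert NoiseConfig().i_max(16000.0) == 320
        assert NoiseConfig(grid_base_frequency=60.0).i_max(16000.0) == 267

    def test_first_harmonic_amplitude(self, setup):
        # amplitude of the 50 Hz component is 0.03 * A_ts * exp(-0.25)
        s = self._series(setup)  # 32000 points -> 50 Hz is exactly bin 100
        a_ts = np.max(s.samples) - np.min(s.samples)
        noise = add_power_grid_noise(s, NoiseConfig(seed=9)).samples - s.samples
        spec = np.fft.rfft(noise) / len(noise) * 2
        measured = np.abs(spec[100])
        assert measured == pytest.approx(0.03 * a_ts * np.exp(-0.25), rel=1e-6)

    def test_constant_series_degenerate(self):
        s = TimeSeries(np.ones(4096), 16000.0)
        with pytest.raises(DegenerateInputError):
            add_power_grid_noise(s, NoiseConfig(seed=0))

    def test_tiled_path_matches_direct_formula(self, setup):
        # fs/base integer -> tiled evaluation; check against the literal sum
        s = TimeSeries(np.sin(np.arange(1000)), 16000.0)
        cfg = NoiseConfig(seed=4)
        noise = add_power_grid_noise(s, cfg).samples - s.samples
        a_ts = np.max(s.samples) - np.min(s.samples)
        i_max = cfg.i_max(16000.0)
        rng = np.random.default_rng(4)
        phases = rng.uniform(0, 2 * np.pi, i_max)
        t = np.arange(1000) / 16000.0
        direct = np.zeros(1000)
        for i in range(1, i_max + 1):
            direct += (
                0.03 * a_ts * np.exp(-0.25 * i) * np.sin(2 * np.pi * 50 * i * t + phases[i - 1])
            )
        assert np.allclose(noise, direct, atol=1e-9)


class TestRandomNoise:
    def test_zero_components_is_identity(self, setup):
        cfg = SynthesisConfig(diameter=500e-9, n_points=4096, n_freqs=2049, seed=3)
        s = generate_clean_series(setup, cfg)
        out = add_random_noise(s, NoiseConfig(n_rnd=0, seed=1))
        assert np.array_equal(out.samples, s.samples)

    def test_component_amplitude_decay(self):
        # component i=300 has amplitude 0.01 * A_ts * exp(-1.5)
        cfg = NoiseConfig()
        amp_300 = cfg.rnd_amp_coeff * np.exp(-cfg.rnd_decay * 300)
        assert amp_300 == pytest.approx(0.002231, rel=1e-3)

    def test_variance_increases_in_expectation(self, setup):
        cfg = SynthesisConfig(diameter=500e-9, n_points=4096, n_freqs=2049, seed=8)
        s = generate_clean_series(setup, cfg)
        base = np.var(s.samples)
        deltas = []
        for seed in range(50):
            out = add_random_noise(s, NoiseConfig(seed=seed))
            deltas.append(np.var(out.samples) - base)
        # independent sinusoids add nonnegative power on average
        assert np.mean(deltas) > 0


class TestNoisePipeline:
    def test_noisy_minus_clean_is_exactly_the_noise(self, setup):
        cfg = SynthesisConfig(diameter=1e-6, n_points=4096, n_freqs=2049, seed=21)
        noise_cfg = NoiseConfig()
        noisy = generate_noisy_series(setup, cfg, noise_cfg)
        s_synth, s_grid, s_rnd = (
            int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(3)
        )
        clean = generate_clean_series(setup, replace(cfg, seed=s_synth))
        with_grid = add_power_grid_noise(clean, replace(noise_cfg, seed=s_grid))
        full = add_random_noise(with_grid, replace(noise_cfg, seed=s_rnd))
        assert np.array_equal(noisy.samples, full.samples)
        assert noisy.origin == "simulated-noisy"


class TestDiameterGrid:
    @pytest.mark.parametrize(
        "step_nm,expected,hits_end",
        [(0.5, 11951, True), (5.0, 1196, True), (50.0, 120, False)],
    )
    def test_grid_sizes(self, step_nm, expected, hits_end):
        grid = diameter_grid(25e-9, 6000e-9, step_nm * 1e-9)
        assert len(grid) == expected
        assert grid[0] == pytest.approx(25e-9)
        if hits_end:
            assert grid[-1] == pytest.approx(6000e-9)
        else:
            assert grid[-1] <= 6000e-9

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ConfigError):
            diameter_grid(1e-6, 1e-6, 1e-9)


class TestTrainingCorpus:
    def test_too_small_grid_refused(self, setup):
        with pytest.raises(ConfigError, match="70/15/15"):
            generate_training_corpus(
                setup, d_min=1e-6, d_max=2e-6, step=0.5e-6, master_seed=0
            )

    def test_determinism_and_structure(self, setup):
        kwargs = dict(d_min=100e-9, d_max=1500e-9, step=100e-9, master_seed=99)
        a = generate_training_corpus(setup, **kwargs)
        b = generate_training_corpus(setup, **kwargs)
        assert np.array_equal(a.acr_matrix, b.acr_matrix)
        assert np.array_equal(a.diameters_reference, b.diameters_reference)
        assert a.n_series == 15 and a.n_lags == 350
        assert np.all(np.diff(a.diameters_true) > 0)
        # every row is a normalized curve anchored at 1
        assert np.allclose(a.acr_matrix[:, 0], 1.0)

    def test_hdf5_and_csv_roundtrip(self, small_corpus, tmp_path):
        from dlsann import TrainingCorpus

        h5 = tmp_path / "corpus.h5"
        small_corpus.save_hdf5(h5)
        back = TrainingCorpus.load_hdf5(h5)
        assert np.array_equal(back.acr_matrix, small_corpus.acr_matrix)
        assert back.setup == small_corpus.setup

        csv = tmp_path / "corpus.csv"
        small_corpus.to_csv(csv)
        back2 = TrainingCorpus.from_csv(csv, small_corpus.setup)
        assert np.allclose(back2.acr_matrix, small_corpus.acr_matrix)
        assert np.allclose(back2.diameters_reference, small_corpus.diameters_reference)


class TestTimeSeriesType:
    def test_too_short_rejected(self):
        with pytest.raises(InputSizeError):
            TimeSeries(np.array([1.0]), 16000.0)

    def test_non_finite_rejected(self):
        with pytest.raises(DegenerateInputError):
            TimeSeries(np.array([1.0, np.nan, 2.0]), 16000.0)

    def test_duration(self):
        s = TimeSeries(np.zeros(128000), 16000.0)
        assert s.duration == pytest.approx(8.0)
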