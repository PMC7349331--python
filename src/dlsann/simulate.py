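"""Synthetic DLS time-series generation and the training corpus.

A mono-dispersed suspension of Brownian scatterers produces a scattered
intensity whose power spectrum is a Lorentzian of half-width a1 = 2*D*q^2.
Clean series are synthesised as a sum of harmonics with amplitudes
sqrt(S(f_i)) on an equally spaced frequency grid and i.i.d. uniform random
phases:

    x(t) = sum_i sqrt(S(f_i)) * sin(2*pi*f_i*t + phi_i)

Realistic measurement noise is then layered on top:

* power-grid noise — 50 Hz and its harmonics, amplitudes decaying
  exponentially with the harmonic number;
* broadband random noise — a few hundred sinusoids at uniformly random
  frequencies with exponentially damped amplitudes.

Both noise amplitudes scale with the peak-to-peak amplitude of the series
they are added to, so the signal-to-noise ratio is size-independent.

The training corpus pairs the 350-lag normalised autocorrelation of one
noisy series per diameter with that diameter (and with the diameter
recovered by the reference single-exponential fit, which is what the
network is actually trained against).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, InputSizeError
from .physics import (
    LorentzianParams,
    OpticalSetup,
    halfwidth_from_diameter,
    lorentzian_spectrum,
)

Origin = Literal["simulated-clean", "simulated-noisy", "recorded"]


@dataclass
class TimeSeries:
    """A uniformly sampled scattered-intensity sequence."""

    samples: np.ndarray
    sampling_frequency: float
    origin: Origin = "recorded"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InputSizeError(
                f"a time-series needs >= 2 samples in one dimension, "
                f"got shape {self.samples.shape}"
            )
        if not self.sampling_frequency > 0:
            raise ConfigError(f"sampling_frequency must be > 0, got {self.sampling_frequency}")
        if not np.all(np.isfinite(self.samples)):
            raise DegenerateInputError("time-series contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_frequency

    def times(self) -> np.ndarray:
        """Sample times t_k = k / f_s, seconds."""
        return np.arange(self.samples.size) / self.sampling_frequency


@dataclass
class SynthesisConfig:
    """Parameters of the clean spectral synthesis.

    ``n_freqs`` must equal ``n_points // 2 + 1`` (the real-spectrum bin
    count) so the harmonic sum maps exactly onto an inverse real FFT.
    """

    diameter: float = 500e-9
    n_points: int = 32768
    n_freqs: int = 16385
    a0: float = 50.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2 or self.n_freqs < 2:
            raise ConfigError("n_points and n_freqs must both be >= 2")
        if not self.diameter > 0:
            raise ConfigError(f"diameter must be > 0, got {self.diameter}")
        if not self.a0 > 0:
            raise ConfigError(f"a0 must be > 0, got {self.a0}")

    def validate_spectral(self) -> None:
        if self.n_freqs != self.n_points // 2 + 1:
            raise ConfigError(
                f"spectral synthesis requires n_freqs == n_points//2 + 1; "
                f"got n_freqs={self.n_freqs}, n_points={self.n_points}"
            )


@dataclass
class NoiseConfig:
    """Power-grid and broadband noise parameters.

    Grid noise injects ``i_max = round(f_s / grid_base_frequency)`` harmonics
    of the base frequency with amplitudes
    ``grid_amp_coeff * A_ts * exp(-grid_decay * i)``; components above the
    Nyquist frequency alias, as they would in a real acquisition. Broadband
    noise adds ``n_rnd`` sinusoids at frequencies uniform in [1, f_s] with
    amplitudes ``rnd_amp_coeff * A_ts * exp(-rnd_decay * i)``. ``A_ts`` is
    the peak-to-peak amplitude of the series the noise is added to.
    """

    grid_base_frequency: float = 50.0
    grid_amp_coeff: float = 0.03
    grid_decay: float = 0.25
    rnd_amp_coeff: float = 0.01
    rnd_decay: float = 0.005
    n_rnd: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_base_frequency", "grid_decay", "rnd_decay"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("grid_amp_coeff", "rnd_amp_coeff"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_rnd < 0:
            raise ConfigError(f"n_rnd must be >= 0, got {self.n_rnd}")

    def i_max(self, sampling_frequency: float) -> int:
        """Number of grid harmonics: round(f_s / base)."""
        return int(round(sampling_frequency / self.grid_base_frequency))


# ---------------------------------------------------------------------------
# clean synthesis
# ---------------------------------------------------------------------------


def _frequency_grid(setup: OpticalSetup, cfg: SynthesisConfig) -> np.ndarray:
    """rfft bin frequencies f_i = i * f_s / n_points, i = 0..n_freqs-1."""
    return np.arange(cfg.n_freqs) * (setup.sampling_frequency / cfg.n_points)


def _amplitudes_and_phases(
    setup: OpticalSetup, cfg: SynthesisConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    freqs = _frequency_grid(setup, cfg)
    a1 = halfwidth_from_diameter(setup, cfg.diameter)
    amps = np.sqrt(lorentzian_spectrum(LorentzianParams(cfg.a0, a1), freqs))
    phases = np.random.default_rng(cfg.seed).uniform(0.0, 2.0 * np.pi, cfg.n_freqs)
    return freqs, amps, phases


def generate_clean_series(setup: OpticalSetup, cfg: SynthesisConfig) -> TimeSeries:
    """Synthesise a clean series via the inverse real FFT.

    Exactly equal (to rounding) to the direct harmonic summation of
    :func:`generate_clean_series_direct`; validated against it in the tests.
    """
    cfg.validate_spectral()
    _, amps, phases = _amplitudes_and_phases(setup, cfg)
    n = cfg.n_points
    # sin(theta + phi) = Re{ e^{j(phi - pi/2)} e^{j theta} }
    spectrum = np.empty(cfg.n_freqs, dtype=complex)
    spectrum[1:-1] = (n / 2.0) * amps[1:-1] * np.exp(1j * (phases[1:-1] - np.pi / 2.0))
    spectrum[0] = n * amps[0] * np.sin(phases[0])  # constant (DC) term
    spectrum[-1] = n * amps[-1] * np.sin(phases[-1])  # Nyquist term: sin(phi)*(-1)^k
    x = np.fft.irfft(spectrum, n=n) + cfg.offset
    return TimeSeries(x, setup.sampling_frequency, origin="simulated-clean")


def generate_clean_series_direct(setup: OpticalSetup, cfg: SynthesisConfig) -> TimeSeries:
    """Literal O(N * N_f) harmonic summation; slow reference implementation."""
    freqs, amps, phases = _amplitudes_and_phases(setup, cfg)
    t = np.arange(cfg.n_points) / setup.sampling_frequency
    x = np.zeros(cfg.n_points)
    for a, f, phi in zip(amps, freqs, phases):
        x += a * np.sin(2.0 * np.pi * f * t + phi)
    return TimeSeries(x + cfg.offset, setup.sampling_frequency, origin="simulated-clean")


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def _peak_to_peak(series: TimeSeries) -> float:
    a_ts = float(np.max(series.samples) - np.min(series.samples))
    if a_ts <= 0:
        raise DegenerateInputError(
            "constant series: peak-to-peak amplitude A_ts is zero, noise scale undefined"
        )
    return a_ts


def add_power_grid_noise(series: TimeSeries, cfg: NoiseConfig) -> TimeSeries:
    """Add the 50 Hz (by default) grid-harmonic noise to a series."""
    if cfg.grid_amp_coeff == 0.0:
        return replace(series, samples=series.samples.copy())
    a_ts = _peak_to_peak(series)
    fs = series.sampling_frequency
    n = len(series)
    i_max = cfg.i_max(fs)
    if i_max < 1:
        return replace(series, samples=series.samples.copy())
    harmonics = np.arange(1, i_max + 1)
    amps = cfg.grid_amp_coeff * a_ts * np.exp(-cfg.grid_decay * harmonics)
    phases = np.random.default_rng(cfg.seed).uniform(0.0, 2.0 * np.pi, i_max)

    period = fs / cfg.grid_base_frequency
    if abs(period - round(period)) < 1e-9:
        # All harmonics of base are periodic over m = f_s/base samples, so one
        # m-sample block suffices and is tiled over the record.
        m = int(round(period))
        k = np.arange(m)
        block = amps @ np.sin(
            2.0 * np.pi * np.outer(harmonics, k) / m + phases[:, None]
        )
        noise = block[np.arange(n) % m]
    else:
        t = series.times()
        noise = amps @ np.sin(
            2.0 * np.pi * cfg.grid_base_frequency * np.outer(harmonics, t)
            + phases[:, None]
        )
    return replace(series, samples=series.samples + noise, origin="simulated-noisy"
                   if series.origin.startswith("simulated") else series.origin)


def add_random_noise(series: TimeSeries, cfg: NoiseConfig) -> TimeSeries:
    """Add broadband random-sinusoid noise to a series."""
    if cfg.n_rnd == 0 or cfg.rnd_amp_coeff == 0.0:
        return replace(series, samples=series.samples.copy())
    a_ts = _peak_to_peak(series)
    fs = series.sampling_frequency
    rng = np.random.default_rng(cfg.seed)
    idx = np.arange(1, cfg.n_rnd + 1)
    amps = cfg.rnd_amp_coeff * a_ts * np.exp(-cfg.rnd_decay * idx)
    freqs = rng.uniform(1.0, fs, cfg.n_rnd)
    phases = rng.uniform(0.0, 2.0 * np.pi, cfg.n_rnd)
    t = series.times()
    noise = amps @ np.sin(2.0 * np.pi * np.outer(freqs, t) + phases[:, None])
    return replace(series, samples=series.samples + noise, origin="simulated-noisy"
                   if series.origin.startswith("simulated") else series.origin)


def generate_noisy_series(
    setup: OpticalSetup,
    cfg: SynthesisConfig,
    noise: NoiseConfig | None = None,
) -> TimeSeries:
    """Clean synthesis followed by grid noise then random noise.

    The peak-to-peak scale of the grid noise is taken from the clean series,
    that of the random noise from the grid-noised series (each noise stage
    sees the series as it stands). Sub-seeds for the three stages are derived
    deterministically from ``cfg.seed``.
    """
    s_synth, s_grid, s_rnd = (
        int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(3)
    )
    noise = noise if noise is not None else NoiseConfig()
    clean = generate_clean_series(setup, replace(cfg, seed=s_synth))
    with_grid = add_power_grid_noise(clean, replace(noise, seed=s_grid))
    return add_random_noise(with_grid, replace(noise, seed=s_rnd))


# ---------------------------------------------------------------------------
# training corpus
# ---------------------------------------------------------------------------


@dataclass
class TrainingCorpus:
    """Normalised 350-lag autocorrelations paired with ground-truth and
    reference-fit diameters, one row per simulated diameter."""

    acr_matrix: np.ndarray  # (n_series, n_lags)
    diameters_true: np.ndarray  # m
    diameters_reference: np.ndarray  # m, from the reference fit
    setup: OpticalSetup
    seeds: np.ndarray  # per-series synthesis seeds

    def __post_init__(self) -> None:
        self.acr_matrix = np.asarray(self.acr_matrix, dtype=float)
        self.diameters_true = np.asarray(self.diameters_true, dtype=float)
        self.diameters_reference = np.asarray(self.diameters_reference, dtype=float)
        self.seeds = np.asarray(self.seeds, dtype=np.int64)
        n = self.acr_matrix.shape[0]
        if not (len(self.diameters_true) == len(self.diameters_reference) == len(self.seeds) == n):
            raise ConfigError("corpus arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.acr_matrix)):
            raise DegenerateInputError("corpus ACR matrix contains non-finite values")
        if n > 1 and not np.all(np.diff(self.diameters_true) > 0):
            raise ConfigError("corpus diameters must be strictly increasing")

    @property
    def n_series(self) -> int:
        return self.acr_matrix.shape[0]

    @property
    def n_lags(self) -> int:
        return self.acr_matrix.shape[1]

    # -- persistence --------------------------------------------------------

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("acr_matrix", data=self.acr_matrix)
            h5.create_dataset("diameters_true", data=self.diameters_true)
            h5.create_dataset("diameters_reference", data=self.diameters_reference)
            h5.create_dataset("seeds", data=self.seeds)
            grp = h5.create_group("setup")
            for k in (
                "wavelength_vacuum",
                "refractive_index",
                "scattering_angle",
                "temperature",
                "viscosity",
                "sampling_frequency",
            ):
                grp.attrs[k] = getattr(self.setup, k)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "TrainingCorpus":
        with h5py.File(path, "r") as h5:
            setup = OpticalSetup(**{k: float(v) for k, v in h5["setup"].attrs.items()})
            return cls(
                acr_matrix=h5["acr_matrix"][...],
                diameters_true=h5["diameters_true"][...],
                diameters_reference=h5["diameters_reference"][...],
                setup=setup,
                seeds=h5["seeds"][...],
            )

    def to_csv(self, path: str | Path) -> None:
        """Flat CSV: diameter_true_m, diameter_reference_m, seed, acr_000..."""
        cols = {f"acr_{k:03d}": self.acr_matrix[:, k] for k in range(self.n_lags)}
        df = pd.DataFrame(
            {
                "diameter_true_m": self.diameters_true,
                "diameter_reference_m": self.diameters_reference,
                "seed": self.seeds,
                **cols,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, setup: OpticalSetup) -> "TrainingCorpus":
        df = pd.read_csv(path)
        acr_cols = sorted(c for c in df.columns if c.startswith("acr_"))
        return cls(
            acr_matrix=df[acr_cols].to_numpy(),
            diameters_true=df["diameter_true_m"].to_numpy(),
            diameters_reference=df["diameter_reference_m"].to_numpy(),
            setup=setup,
            seeds=df["seed"].to_numpy(),
        )


def diameter_grid(d_min: float, d_max: float, step: float) -> np.ndarray:
    """Arithmetic grid d_min, d_min+step, ... up to and including d_max when
    the span is an exact multiple of the step."""
    if not (d_min > 0 and d_max > d_min and step > 0):
        raise ConfigError("require 0 < d_min < d_max and step > 0")
    n = int(np.floor((d_max - d_min) / step + 1e-9)) + 1
    return d_min + step * np.arange(n)


def generate_training_corpus(
    setup: OpticalSetup,
    d_min: float = 25e-9,
    d_max: float = 6000e-9,
    step: float = 0.5e-9,
    synthesis: SynthesisConfig | None = None,
    noise: NoiseConfig | None = None,
    master_seed: int = 0,
    n_lags: int = 350,
    with_reference_fit: bool = True,
    add_noise: bool = True,
) -> TrainingCorpus:
    """Generate one noisy series per grid diameter and assemble the corpus.

    Per-series seeds are drawn once from ``SeedSequence(master_seed)`` so each
    row is independently reproducible. Refuses grids of fewer than 10 series
    (too small for a 70/15/15 split).
    """
    from .acr import normalized_acr  # local import to avoid a cycle
    from .reference import fit_single_exponential

    diameters = diameter_grid(d_min, d_max, step)
    if len(diameters) < 10:
        raise ConfigError(
            f"diameter grid yields only {len(diameters)} series; need >= 10 "
            "to support a 70/15/15 split"
        )
    synthesis = synthesis if synthesis is not None else SynthesisConfig()
    seeds = np.random.SeedSequence(master_seed).generate_state(len(diameters)).astype(np.int64)

    acr_rows = np.empty((len(diameters), n_lags))
    d_ref = np.full(len(diameters), np.nan)
    for i, d in enumerate(diameters):
        cfg = replace(synthesis, diameter=float(d), seed=int(seeds[i]))
        if add_noise:
            series = generate_noisy_series(setup, cfg, noise)
        else:
            s_synth = int(np.random.SeedSequence(cfg.seed).generate_state(3)[0])
            series = generate_clean_series(setup, replace(cfg, seed=s_synth))
        curve = normalized_acr(series, n_lags=n_lags)
        acr_rows[i] = curve.lag_values
        if with_reference_fit:
            d_ref[i] = fit_single_exponential(curve, setup).diameter
    return TrainingCorpus(
        acr_matrix=acr_rows,
        diameters_true=diameters,
        diameters_reference=d_ref,
        setup=setup,
        seeds=seeds,
    )
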