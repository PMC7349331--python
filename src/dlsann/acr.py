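"""Intensity autocorrelation estimation and normalization.

The raw estimator is the sample autocorrelation of the intensity without
mean removal,

    G[k] = (1/(N-k)) * sum_{t=0}^{N-1-k} x[t] * x[t+k],

because the constant baseline B of the DLS correlation model is part of
the raw curve and is removed explicitly by the two-step normalization:

1. the baseline B_hat — the mean of the curve over its last 10% of lags —
   is subtracted;
2. the curve is divided by A_hat, the amplitude at zero lag of the
   *decaying* (coherent) component, and the lag-0 value is set to 1.

Step 2 is the software counterpart of the experimental spatial-coherence
adjustment (detector matched to one speckle): it makes the coherence
factor of the coherent signal unity.  A_hat is estimated by a
deterministic amplitude-profiled exponential fit over lags >= 1, rather
than read off G[0], because broadband measurement noise adds variance
that decorrelates within a single lag: it inflates G[0] without touching
the rest of the curve, and anchoring at G[0] would rescale (and bias)
the entire decay.  For a mono-dispersed suspension the normalized curve
is then the single exponential g[k] = exp(-2*D*q^2 * tau_k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputSizeError, NormalizationError
from .simulate import TimeSeries

#: Fraction of trailing lags used for the baseline estimate B_hat.
BASELINE_TAIL_FRACTION = 0.1

#: Lags computed internally per retained lag, so the baseline window sits
#: past the exponential decay over the whole supported size range (at 16 kHz
#: a 6 um particle has decayed to ~1e-4 by lag 8*350).
INTERNAL_LAG_FACTOR = 8


@dataclass
class AutocorrelationCurve:
    """Lagged autocorrelation values at spacing ``lag_spacing`` seconds."""

    lag_values: np.ndarray
    lag_spacing: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.lag_values = np.asarray(self.lag_values, dtype=float)
        if self.lag_values.ndim != 1 or self.lag_values.size < 2:
            raise InputSizeError("an autocorrelation curve needs >= 2 lags")
        if not self.lag_spacing > 0:
            raise InputSizeError(f"lag_spacing must be > 0, got {self.lag_spacing}")
        if not np.all(np.isfinite(self.lag_values)):
            raise InputSizeError("autocorrelation curve contains non-finite values")

    @property
    def n_lags(self) -> int:
        return self.lag_values.size

    def lag_times(self) -> np.ndarray:
        """tau_k = k * lag_spacing, seconds."""
        return np.arange(self.n_lags) * self.lag_spacing

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"lag_seconds": self.lag_times(), "value": self.lag_values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalized: bool = True) -> "AutocorrelationCurve":
        df = pd.read_csv(path)
        lag = df["lag_seconds"].to_numpy()
        if len(lag) < 2:
            raise InputSizeError(f"ACR file {path} has fewer than 2 lags")
        return cls(df["value"].to_numpy(), float(lag[1] - lag[0]), normalized=normalized)


def autocorrelation(series: TimeSeries, n_lags: int = 350) -> AutocorrelationCurve:
    """Raw autocorrelation of the intensity at lags 0..n_lags-1.

    FFT-based (zero padded to avoid circular wrap); no mean removal.
    """
    x = series.samples
    n = x.size
    if n <= n_lags:
        raise InputSizeError(
            f"series of length {n} is too short for {n_lags} lags (need > n_lags)"
        )
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n_lags]
    # divide by the actual number of products at each lag, so a constant
    # series c gives a flat curve at c^2 and the estimator is unbiased for
    # stationary signals (no (1 - k/N) taper across the lag window)
    counts = n - np.arange(n_lags)
    return AutocorrelationCurve(
        acov / counts, lag_spacing=1.0 / series.sampling_frequency, normalized=False
    )


def estimate_baseline(curve: AutocorrelationCurve) -> float:
    """Baseline B_hat: mean of the last ``BASELINE_TAIL_FRACTION`` of the lags."""
    n_tail = max(1, int(round(BASELINE_TAIL_FRACTION * curve.n_lags)))
    return float(np.mean(curve.lag_values[-n_tail:]))


def estimate_amplitude_baseline(
    g: np.ndarray, tau: np.ndarray, fit_baseline: bool = True
) -> tuple[float, float]:
    """Coherent amplitude A_hat and baseline B_hat of a raw curve, by a
    profiled single-exponential-plus-constant fit over lags >= 1.

    For each candidate decay rate gamma, the model ``A*exp(-gamma*tau) + B``
    is linear in (A, B) and solved in closed form; a coarse log-spaced scan
    over gamma is followed by bounded refinement.  Deterministic; requires
    no knowledge of the optical setup.  Using every internal lag makes both
    estimates far less noisy than reading the curve at single points.
    """
    from scipy.optimize import minimize_scalar

    yk = g[1:]
    tk = tau[1:]
    n = yk.size
    sy = float(np.sum(yk))

    def solve(m: np.ndarray) -> tuple[float, float, float]:
        smm = float(m @ m)
        smy = float(m @ yk)
        if not fit_baseline:
            a = smy / smm
            r = yk - a * m
            return a, 0.0, float(r @ r)
        sm = float(np.sum(m))
        det = smm * n - sm * sm
        if det <= 0:
            return 0.0, sy / n, float(np.sum((yk - sy / n) ** 2))
        a = (n * smy - sm * sy) / det
        b = (smm * sy - sm * smy) / det
        r = yk - a * m - b
        return a, b, float(r @ r)

    # decay rates from "flat over the window" to "gone within one lag"
    gammas = np.geomspace(0.01 / tk[-1], 8.0 / tk[0], 200)
    models = np.exp(-np.outer(gammas, tk))
    smm = np.einsum("ij,ij->i", models, models)
    smy = models @ yk
    if fit_baseline:
        sm = models.sum(axis=1)
        det = smm * n - sm * sm
        det = np.where(det > 0, det, np.inf)
        a = (n * smy - sm * sy) / det
        b = (smm * sy - sm * smy) / det
    else:
        a = smy / smm
        b = np.zeros_like(a)
    sse = np.sum((a[:, None] * models + b[:, None] - yk) ** 2, axis=1)
    k = int(np.argmin(sse))
    lo, hi = gammas[max(k - 1, 0)], gammas[min(k + 1, len(gammas) - 1)]
    res = minimize_scalar(
        lambda g_: solve(np.exp(-g_ * tk))[2], bounds=(lo, hi), method="bounded",
        options={"xatol": gammas[k] * 1e-9, "maxiter": 200},
    )
    if res.fun <= sse[k]:
        a_best, b_best, _ = solve(np.exp(-float(res.x) * tk))
    else:
        a_best, b_best = float(a[k]), float(b[k])
    return float(a_best), float(b_best)


def normalize_acr(
    curve: AutocorrelationCurve,
    baseline: float | None = None,
    n_keep: int | None = None,
) -> AutocorrelationCurve:
    """Two-step normalization: subtract B_hat, divide by the coherent
    amplitude A_hat, anchor the lag-0 value to 1.

    Idempotent: the tail mean of an already-normalized curve is exactly zero
    (same tail window) and its coherent amplitude is unity, so a second
    application reproduces the curve to rounding.
    """
    if curve.n_lags < 50:
        raise InputSizeError(
            f"need >= 50 lags to estimate the baseline, got {curve.n_lags}"
        )
    if baseline is not None:
        y = curve.lag_values - float(baseline)
        a_hat, _ = estimate_amplitude_baseline(y, curve.lag_times(), fit_baseline=False)
    else:
        a_hat, b_hat = estimate_amplitude_baseline(curve.lag_values, curve.lag_times())
        y = curve.lag_values - b_hat
    if a_hat <= 0:
        raise NormalizationError(
            "degenerate normalization: coherent amplitude A_hat <= 0 "
            "(flat curve or no decaying component)"
        )
    values = y / a_hat
    values[0] = 1.0
    if n_keep is not None:
        if n_keep > curve.n_lags:
            raise InputSizeError(f"cannot keep {n_keep} of {curve.n_lags} lags")
        values = values[:n_keep]
    return AutocorrelationCurve(values, curve.lag_spacing, normalized=True)


def normalized_acr(series: TimeSeries, n_lags: int = 350) -> AutocorrelationCurve:
    """Convenience pipeline: raw ACR over ``INTERNAL_LAG_FACTOR * n_lags`` lags,
    baseline from the tail of that longer window, then the first ``n_lags``
    normalized lags."""
    raw = autocorrelation(series, n_lags=INTERNAL_LAG_FACTOR * n_lags)
    return normalize_acr(raw, n_keep=n_lags)
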