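"""Reference DLS sizing: least-squares fit of the single-exponential decay.

The normalized autocorrelation of a mono-dispersed suspension is
``g(tau) = exp(-2*D*q^2*tau)`` with ``D = k_B*T/(3*pi*eta*d)``, so the fit
has the hydrodynamic diameter ``d`` as its single free parameter. The
optimizer is deterministic: a coarse scan over log-spaced diameters
followed by bounded scalar minimization around the best grid point, which
removes any sensitivity to a starting guess.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .acr import AutocorrelationCurve
from .errors import ParameterDomainError, StateError
from .physics import OpticalSetup, diffusion_coefficient, scattering_vector_modulus

#: Default search bounds (m) and coarse-grid size.
DEFAULT_SEARCH_RANGE = (10e-9, 20e-6)
COARSE_GRID_POINTS = 200


@dataclass
class FitResult:
    """Outcome of a single-exponential fit."""

    diameter: float  # m
    diffusion: float  # m^2/s
    residual_sse: float
    n_lags_used: int
    converged: bool


def expected_acr(
    setup: OpticalSetup, diameter: float, n_lags: int = 350
) -> AutocorrelationCurve:
    """Analytic normalized curve exp(-2*D*q^2*tau_k) for a given diameter."""
    q = scattering_vector_modulus(setup)
    gamma = 2.0 * diffusion_coefficient(setup, diameter) * q * q
    tau = np.arange(n_lags) / setup.sampling_frequency
    return AutocorrelationCurve(
        np.exp(-gamma * tau), lag_spacing=1.0 / setup.sampling_frequency, normalized=True
    )


def _sse(curve_values: np.ndarray, tau: np.ndarray, gamma_per_inv_d: float, d: float) -> float:
    model = np.exp(-(gamma_per_inv_d / d) * tau)
    r = curve_values - model
    return float(r @ r)


def fit_single_exponential(
    curve: AutocorrelationCurve,
    setup: OpticalSetup,
    search_range: Sequence[float] = DEFAULT_SEARCH_RANGE,
) -> FitResult:
    """Fit exp(-2*D(d)*q^2*tau) to a normalized curve; returns the best d.

    Deterministic two-stage minimization (coarse log grid, then bounded
    refinement between the grid neighbours of the best point). A minimizer
    at the search boundary is flagged ``converged=False`` but still returned.
    """
    if not curve.normalized:
        raise StateError("fit requires a normalized autocorrelation curve")
    d_lo, d_hi = float(search_range[0]), float(search_range[1])
    if not (0 < d_lo < d_hi):
        raise ParameterDomainError(f"invalid search range: {search_range!r}")

    q = scattering_vector_modulus(setup)
    # gamma(d) = 2*D(d)*q^2 = C/d with C = 2*k_B*T*q^2/(3*pi*eta)
    c = 2.0 * diffusion_coefficient(setup, 1.0) * q * q
    tau = curve.lag_times()
    y = curve.lag_values

    grid = np.geomspace(d_lo, d_hi, COARSE_GRID_POINTS)
    # vectorized coarse scan
    models = np.exp(-np.outer(c / grid, tau))
    sse = np.sum((models - y) ** 2, axis=1)
    k = int(np.argmin(sse))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]

    res = minimize_scalar(
        lambda d: _sse(y, tau, c, d),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": grid[k] * 1e-9, "maxiter": 200},
    )
    d_best, f_best = float(res.x), float(res.fun)
    if sse[k] < f_best:  # refinement should never lose to the grid
        d_best, f_best = float(grid[k]), float(sse[k])

    rel_edge = 1e-6
    at_boundary = d_best <= d_lo * (1 + rel_edge) or d_best >= d_hi * (1 - rel_edge)
    return FitResult(
        diameter=d_best,
        diffusion=diffusion_coefficient(setup, d_best),
        residual_sse=f_best,
        n_lags_used=curve.n_lags,
        converged=not at_boundary,
    )


def batch_reference_fit(
    curves: Iterable[AutocorrelationCurve],
    setup: OpticalSetup,
    search_range: Sequence[float] = DEFAULT_SEARCH_RANGE,
) -> list[FitResult]:
    """Fit every curve; per-curve failures become non-converged NaN rows
    rather than aborting the batch."""
    results: list[FitResult] = []
    for curve in curves:
        try:
            results.append(fit_single_exponential(curve, setup, search_range))
        except Exception:
            results.append(
                FitResult(
                    diameter=float("nan"),
                    diffusion=float("nan"),
                    residual_sse=float("nan"),
                    n_lags_used=getattr(curve, "n_lags", 0),
                    converged=False,
                )
            )
    return results
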