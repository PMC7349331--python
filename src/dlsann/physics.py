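"""Closed-form optics and diffusion relations for dynamic light scattering.

A DLS experiment probes the Brownian diffusion of suspended scatterers
through the temporal fluctuations of coherently scattered light.  The link
between the measurable decay rate of those fluctuations and the particle
size runs through three classical relations:

* the scattering vector modulus ``q = 4*pi*n/lambda * sin(theta/2)``,
  which sets the spatial frequency the geometry probes;
* the Einstein–Stokes relation ``D = k_B*T / (3*pi*eta*d)`` between the
  diffusion coefficient and the hydrodynamic diameter ``d``;
* the Lorentzian power spectrum of the scattered intensity,
  ``S(f) = a0*a1 / ((2*pi*f)^2 + a1^2)``, whose half-width
  ``a1 = 2*D*q^2`` (rad/s) encodes the diffusion coefficient.

Everything here is exact arithmetic on those formulas; all quantities are
SI internally (metres, kelvin, pascal-seconds, radians).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterDomainError

#: Boltzmann constant, exact 2019 SI value (J/K).
BOLTZMANN = 1.380649e-23


@dataclass(frozen=True)
class OpticalSetup:
    """Optical and thermodynamic parameters of a DLS experiment.

    Parameters
    ----------
    wavelength_vacuum
        Vacuum wavelength of the laser, metres.
    refractive_index
        Refractive index of the solvent (dimensionless, >= 1).
    scattering_angle
        Scattering angle in radians, strictly inside (0, pi).
    temperature
        Absolute sample temperature, kelvin.
    viscosity
        Dynamic viscosity of the solvent, Pa*s.
    sampling_frequency
        Data-acquisition rate of the detector, Hz.
    """

    wavelength_vacuum: float = 633e-9
    refractive_index: float = 1.331
    scattering_angle: float = math.pi / 2
    temperature: float = 295.15
    viscosity: float = 9.5e-4
    sampling_frequency: float = 16000.0

    def __post_init__(self) -> None:
        checks = [
            ("wavelength_vacuum", self.wavelength_vacuum > 0),
            ("refractive_index", self.refractive_index >= 1),
            ("scattering_angle", 0 < self.scattering_angle < math.pi),
            ("temperature", self.temperature > 0),
            ("viscosity", self.viscosity > 0),
            ("sampling_frequency", self.sampling_frequency > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ParameterDomainError(
                    f"invalid OpticalSetup field {name!r}: {getattr(self, name)!r}"
                )

    # -- flat config (de)serialization --------------------------------------

    def to_config(self, path: str | Path) -> None:
        """Write the setup as a flat YAML mapping (SI units, angle in radians)."""
        data = {
            "wavelength_vacuum": float(self.wavelength_vacuum),
            "refractive_index": float(self.refractive_index),
            "scattering_angle": float(self.scattering_angle),
            "temperature": float(self.temperature),
            "viscosity": float(self.viscosity),
            "sampling_frequency": float(self.sampling_frequency),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_config(cls, path: str | Path) -> "OpticalSetup":
        """Read a flat config file.

        The angle may be given either as ``scattering_angle`` (radians) or as
        ``scattering_angle_degrees``; temperature alternatively as
        ``temperature_celsius``.
        """
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterDomainError(f"config file {path} is not a flat mapping")
        data = dict(data)
        if "scattering_angle_degrees" in data:
            data["scattering_angle"] = math.radians(
                float(data.pop("scattering_angle_degrees"))
            )
        if "temperature_celsius" in data:
            data["temperature"] = float(data.pop("temperature_celsius")) + 273.15
        known = {
            "wavelength_vacuum",
            "refractive_index",
            "scattering_angle",
            "temperature",
            "viscosity",
            "sampling_frequency",
        }
        unknown = set(data) - known
        if unknown:
            raise ParameterDomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class LorentzianParams:
    """Lorentzian spectral-line parameters.

    ``a0`` is an overall amplitude scale (arbitrary units, order of tens);
    ``a1`` is the half-width in rad/s, equal to ``2*D*q^2`` for Brownian
    scatterers.
    """

    a0: float
    a1: float

    def __post_init__(self) -> None:
        if not self.a0 > 0:
            raise ParameterDomainError(f"invalid LorentzianParams field 'a0': {self.a0!r}")
        if not self.a1 > 0:
            raise ParameterDomainError(f"invalid LorentzianParams field 'a1': {self.a1!r}")


def scattering_vector_modulus(setup: OpticalSetup) -> float:
    """Modulus of the scattering vector, ``q = 4*pi*n/lambda * sin(theta/2)`` (1/m)."""
    return (
        4.0
        * math.pi
        * setup.refractive_index
        / setup.wavelength_vacuum
        * math.sin(setup.scattering_angle / 2.0)
    )


def diffusion_coefficient(setup: OpticalSetup, diameter: float) -> float:
    """Einstein–Stokes diffusion coefficient ``D = k_B*T/(3*pi*eta*d)`` (m^2/s)."""
    if not diameter > 0:
        raise ParameterDomainError(f"diameter must be > 0, got {diameter!r}")
    return BOLTZMANN * setup.temperature / (3.0 * math.pi * setup.viscosity * diameter)


def halfwidth_from_diameter(setup: OpticalSetup, diameter: float) -> float:
    """Lorentzian half-width ``a1 = 2*D*q^2`` (rad/s) for a given diameter."""
    q = scattering_vector_modulus(setup)
    return 2.0 * diffusion_coefficient(setup, diameter) * q * q


def diameter_from_halfwidth(setup: OpticalSetup, a1: float) -> float:
    """Hydrodynamic diameter from the half-width: ``d = 2*k_B*T*q^2/(3*pi*eta*a1)``.

    Exact algebraic inverse of :func:`halfwidth_from_diameter`.
    """
    if not a1 > 0:
        raise ParameterDomainError(f"a1 must be > 0, got {a1!r}")
    q = scattering_vector_modulus(setup)
    return 2.0 * BOLTZMANN * setup.temperature * q * q / (3.0 * math.pi * setup.viscosity * a1)


def lorentzian_spectrum(params: LorentzianParams, frequency):
    """Lorentzian spectral density ``S(f) = a0*a1/((2*pi*f)^2 + a1^2)``.

    Accepts a scalar or an array of frequencies (Hz, >= 0); maximal at f=0,
    monotone decreasing in f.
    """
    import numpy as np

    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ParameterDomainError("frequency must be >= 0")
    s = params.a0 * params.a1 / ((2.0 * np.pi * f) ** 2 + params.a1**2)
    return float(s) if np.ndim(frequency) == 0 else s
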