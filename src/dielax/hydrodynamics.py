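"""Rotational-diffusion relaxation times of prolate ellipsoids.

The Stokes-Einstein-Debye (SED) law gives the rotational relaxation time of
a sphere of radius r in a solvent of viscosity eta as 4*pi*eta*r^3/(kB*T).
Perrin's extension covers ellipsoids; for a prolate body with semi-axes
a >= b, axial ratio rho = b/a, and electric dipole parallel to the long
axis, the microscopic rotational time is

    tau_rot = (8*pi*eta*a^3 / 3*kB*T) * (1 - rho^4)
              / [ (2 - rho^2) * L / sqrt(1 - rho^2) - 1 ],
    L = ln((1 + sqrt(1 - rho^2)) / rho).

The measured dielectric relaxation time tau_DR differs from tau_rot by the
macroscopic-field (Powles-Glarum-type) factor 3*eps_s / (2*eps_s + eps_inf),
where eps_s is the static permittivity and eps_inf the high-frequency limit
of the process in question (for the solute L process, the L-process
high-frequency limit, not the full eps_inf of the spectrum).

The ratio of an observed to a predicted time, by SED linearity in eta, reads
as the local viscosity felt by the rotating solute relative to the solvent
used in the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM, K_BOLTZMANN

__all__ = [
    "EllipsoidGeometry",
    "SolventConditions",
    "CorrectionContext",
    "perrin_tau_rot",
    "macroscopic_correction",
    "predict_tau_a",
    "local_viscosity_ratio",
]

#: below this departure of rho from 1 the analytic sphere limit is used
_SPHERE_RHO_TOL = 1e-9


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Prolate solute geometry; ``a`` and ``b`` are SEMI-axes in metres.

    Use :meth:`from_angstrom` for the conventional Å interface.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0 < self.b <= self.a):
            raise ValueError("require 0 < b <= a (prolate or spherical)")

    @classmethod
    def from_angstrom(cls, a: float, b: float) -> "EllipsoidGeometry":
        return cls(a=a * ANGSTROM, b=b * ANGSTROM)

    @property
    def rho(self) -> float:
        """Axial ratio rho = b/a, in (0, 1]."""
        return self.b / self.a


@dataclass(frozen=True)
class SolventConditions:
    """Temperature (K) and solvent viscosity (Pa s).

    Defaults are pure water at 293 K, eta = 1.002 mPa s.
    """

    temperature: float = 293.0
    viscosity: float = 1.002e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")


@dataclass(frozen=True)
class CorrectionContext:
    """Permittivities entering the macroscopic-field correction factor."""

    static_permittivity: float
    high_freq_permittivity: float

    def __post_init__(self) -> None:
        if self.high_freq_permittivity < 1 or self.static_permittivity < 1:
            raise ValueError("permittivities must be >= 1")
        if self.static_permittivity < self.high_freq_permittivity:
            raise ValueError("static permittivity must be >= high-frequency value")

    @property
    def factor(self) -> float:
        """3*eps_s/(2*eps_s + eps_inf), dimensionless, in [1, 1.5)."""
        es, ei = self.static_permittivity, self.high_freq_permittivity
        return 3.0 * es / (2.0 * es + ei)


def perrin_tau_rot(geometry: EllipsoidGeometry, solvent: SolventConditions) -> float:
    """Microscopic rotational relaxation time of a prolate ellipsoid, seconds.

    Dipole parallel to the long axis. Reduces analytically to the Debye
    sphere value 4*pi*eta*r^3/(kB*T) as rho -> 1.
    """
    a, rho = geometry.a, geometry.rho
    eta, T = solvent.viscosity, solvent.temperature
    kT = K_BOLTZMANN * T
    if 1.0 - rho < _SPHERE_RHO_TOL:
        return 4.0 * np.pi * eta * a**3 / kT
    s = np.sqrt(1.0 - rho * rho)
    L = np.log((1.0 + s) / rho)
    shape = (1.0 - rho**4) / ((2.0 - rho * rho) * L / s - 1.0)
    return 8.0 * np.pi * eta * a**3 / (3.0 * kT) * shape


def macroscopic_correction(tau_rot: float, context: CorrectionContext) -> float:
    """Measured dielectric relaxation time tau_DR from the microscopic tau_rot."""
    if tau_rot <= 0:
        raise ValueError("tau_rot must be > 0")
    return context.factor * tau_rot


def predict_tau_a(
    geometry: EllipsoidGeometry,
    solvent: SolventConditions,
    context: CorrectionContext,
) -> float:
    """Predicted dielectric relaxation time tau_a of the solute L process, seconds.

    Composition of :func:`perrin_tau_rot` and :func:`macroscopic_correction`;
    bare geometry, no hydration shell. Round to the nearest picosecond for
    human-readable reporting.
    """
    return macroscopic_correction(perrin_tau_rot(geometry, solvent), context)


def local_viscosity_ratio(tau_observed: float, tau_predicted: float) -> float:
    """tau_obs/tau_pred, read as eta_local/eta_solvent under the SED law."""
    if tau_observed <= 0 or tau_predicted <= 0:
        raise ValueError("relaxation times must be > 0")
    return tau_observed / tau_predicted
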