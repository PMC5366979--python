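"""Forward evaluation of superposed-Debye dielectric relaxation models.

The model is

    eps*(omega) = eps_inf + sum_k  Deps_k / (1 + i*omega*tau_k)

with an optional dc-conductivity contribution sigma_dc/(omega*eps0) added to
the loss channel only. Processes are conventionally labelled L, M, H for the
low-, intermediate- and high-frequency relaxations of aqueous biomolecule
solutions (solute rotation, a small unassigned process, and bulk water).

A symmetric Cole-Cole broadening exponent ``alpha`` is supported per process
(``alpha = 0`` is pure Debye): Deps / (1 + (i*omega*tau)^(1-alpha)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import EPSILON_0

__all__ = [
    "DebyeProcess",
    "RelaxationModel",
    "debye_term",
    "evaluate_model",
    "static_permittivity",
]


@dataclass(frozen=True)
class DebyeProcess:
    """One dipolar relaxation process.

    Parameters
    ----------
    delta_eps
        Relaxation strength Deps > 0 (the drop in eps' across the process).
    tau
        Relaxation time in seconds, > 0. The loss peaks at f = 1/(2*pi*tau).
    label
        Conventional tag; L, M, H for frequency-ordered processes.
    alpha
        Cole-Cole symmetric-broadening exponent in [0, 1); 0 is pure Debye.
    """

    delta_eps: float
    tau: float
    label: str = ""
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (self.delta_eps > 0 and np.isfinite(self.delta_eps)):
            raise ValueError("delta_eps must be finite and > 0")
        if not (self.tau > 0 and np.isfinite(self.tau)):
            raise ValueError("tau must be finite and > 0")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")


@dataclass(frozen=True)
class RelaxationModel:
    """High-frequency limit plus an ordered set of relaxation processes."""

    eps_inf: float
    processes: tuple[DebyeProcess, ...] = ()
    sigma_dc: float = 0.0

    def __post_init__(self) -> None:
        if not (self.eps_inf >= 1.0 and np.isfinite(self.eps_inf)):
            raise ValueError("eps_inf must be finite and >= 1")
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be >= 0")
        procs = tuple(sorted(self.processes, key=lambda p: -p.tau))
        labels = [p.label for p in procs if p.label]
        if len(labels) != len(set(labels)):
            raise ValueError("process labels must be unique")
        object.__setattr__(self, "processes", procs)

    @property
    def eps_static(self) -> float:
        return static_permittivity(self)

    def process(self, label: str) -> DebyeProcess:
        for p in self.processes:
            if p.label == label:
                return p
        raise KeyError(f"no process labelled {label!r}")


def debye_term(process: DebyeProcess, frequency) -> np.ndarray | complex:
    """Complex contribution Deps/(1 + (i*omega*tau)^(1-alpha)) at ``frequency`` (Hz).

    Returns Deps exactly at zero frequency; the imaginary part is
    non-positive (loss-carrying) for all f >= 0.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    iwt = 1j * 2.0 * np.pi * f * process.tau
    if process.alpha == 0.0:
        out = process.delta_eps / (1.0 + iwt)
    else:
        # principal branch; (i*w*tau)^(1-alpha) with (0)^x = 0
        out = process.delta_eps / (1.0 + iwt ** (1.0 - process.alpha))
    if np.isscalar(frequency):
        return complex(out)
    return out


def evaluate_model(model: RelaxationModel, frequencies, **spectrum_kwargs):
    """Evaluate eps'(f) and eps''(f) of ``model`` on a frequency grid.

    Returns a :class:`~dielax.spectra.PermittivitySpectrum`. The dc term
    sigma_dc/(2*pi*f*eps0) is added to the loss channel only and diverges at
    f = 0, so all frequencies must be positive when ``sigma_dc > 0``.
    """
    from .spectra import PermittivitySpectrum  # deferred: spectra imports models

    f = np.asarray(frequencies, dtype=float)
    if model.sigma_dc > 0 and np.any(f <= 0):
        raise ValueError("all frequencies must be > 0 when sigma_dc > 0")
    total = np.full(f.shape, complex(model.eps_inf), dtype=complex)
    for p in model.processes:
        total = total + debye_term(p, f)
    eps_real = total.real
    eps_imag = np.abs(total.imag)
    if model.sigma_dc > 0:
        eps_imag = eps_imag + model.sigma_dc / (2.0 * np.pi * f * EPSILON_0)
    return PermittivitySpectrum(
        frequency=f, eps_real=eps_real, eps_imag=eps_imag, **spectrum_kwargs
    )


def static_permittivity(model: RelaxationModel) -> float:
    """Static permittivity eps_s = eps_inf + sum of relaxation strengths."""
    return model.eps_inf + sum(p.delta_eps for p in model.processes)
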