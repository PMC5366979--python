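"""Synthetic permittivity spectra with realistic measurement noise.

Generates spectra from a relaxation model on log-spaced grids over the
microwave (TDR, 0.5-25 GHz) and terahertz (THz-TDS, 0.3-2.5 THz) bands,
with multiplicative Gaussian noise at the ~+/-3% relative accuracy typical
of TDR permittivity measurements, and optional dc-conductivity
contamination of the low-frequency loss.

Named fixtures provide relaxation models for the study systems. The
L-process parameters of the glycine fixtures (delta_eps = 28.7,
tau = 72 ps, static permittivity 120, L-process high-frequency limit 91.3)
are the measured solution values; the M- and H-process parameters and the
pure-water constants are literature-style stand-ins chosen here (no
measured values are available for them) and nothing downstream depends on
their specific magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import DebyeProcess, RelaxationModel, evaluate_model
from .spectra import PermittivitySpectrum

__all__ = [
    "NoiseSpec",
    "BandSpec",
    "TDR_BAND",
    "THZ_BAND",
    "make_grid",
    "simulate_spectrum",
    "fixture",
    "FIXTURE_NAMES",
]

#: PRNG used for all noise draws (recorded in outputs for reproducibility)
PRNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian amplitude noise, i.i.d. across frequencies."""

    relative_sigma: float = 0.03
    seed: int = 0
    per_channel_independent: bool = True

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")


@dataclass(frozen=True)
class BandSpec:
    """A log-spaced frequency band."""

    f_min: float
    f_max: float
    points_per_decade: int = 10
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ValueError("require 0 < f_min < f_max")
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")


TDR_BAND = BandSpec(5e8, 2.5e10, points_per_decade=20, label="TDR")
THZ_BAND = BandSpec(3e11, 2.5e12, points_per_decade=20, label="THz-TDS")


def make_grid(band: BandSpec) -> np.ndarray:
    """Log-spaced frequency grid including both band endpoints.

    The number of points is ceil(points_per_decade * decades) + 1.
    """
    decades = math.log10(band.f_max / band.f_min)
    n = math.ceil(band.points_per_decade * decades) + 1
    return np.geomspace(band.f_min, band.f_max, n)


def simulate_spectrum(
    model: RelaxationModel, band: BandSpec, noise: NoiseSpec | None = None
) -> PermittivitySpectrum:
    """Evaluate ``model`` on the band grid and apply multiplicative noise.

    Each channel is multiplied pointwise by 1 + N(0, relative_sigma)
    (independent factors per channel unless ``per_channel_independent`` is
    off); the loss channel is truncated at zero. With zero noise the output
    is bit-identical to :func:`~dielax.models.evaluate_model`. Deterministic
    given the noise seed.
    """
    grid = make_grid(band)
    base = evaluate_model(model, grid, band_label=band.label or "synthetic")
    if noise is None or noise.relative_sigma == 0:
        return base
    rng = np.random.default_rng(noise.seed)
    factor_re = 1.0 + rng.normal(0.0, noise.relative_sigma, size=grid.size)
    if noise.per_channel_independent:
        factor_im = 1.0 + rng.normal(0.0, noise.relative_sigma, size=grid.size)
    else:
        factor_im = factor_re
    return PermittivitySpectrum(
        frequency=grid,
        eps_real=base.eps_real * factor_re,
        eps_imag=np.maximum(base.eps_imag * factor_im, 0.0),
        band_label=base.band_label,
        temperature=base.temperature,
    )


def _water_293K() -> RelaxationModel:
    # literature-style pure-water constants at 293 K (stand-ins, see module
    # docstring): eps_s ~ 80.2, tau ~ 9.4 ps, eps_inf ~ 5.3
    return RelaxationModel(
        eps_inf=5.3,
        processes=(DebyeProcess(delta_eps=74.9, tau=9.4e-12, label="H"),),
    )


def _glycine_solution() -> RelaxationModel:
    # L process from the measured 3 mol% glycine solution: eps_s = 120,
    # L-process high-frequency limit 91.3 -> delta_eps_L = 28.7, tau_L = 72 ps.
    # M (small) and H (bulk-water-like) are invented stand-ins.
    return RelaxationModel(
        eps_inf=5.0,
        processes=(
            DebyeProcess(delta_eps=28.7, tau=72e-12, label="L"),
            DebyeProcess(delta_eps=3.0, tau=25e-12, label="M"),
            DebyeProcess(delta_eps=83.3, tau=9.4e-12, label="H"),
        ),
    )


def _collagen_glycine_solution() -> RelaxationModel:
    # identical L (and M) processes: the solute rotation is insensitive to
    # the collagen network; the water strength is reduced by the 4 wt%
    # volume-exclusion decrement (~3.2)
    return RelaxationModel(
        eps_inf=5.0,
        processes=(
            DebyeProcess(delta_eps=28.7, tau=72e-12, label="L"),
            DebyeProcess(delta_eps=3.0, tau=25e-12, label="M"),
            DebyeProcess(delta_eps=80.1, tau=9.4e-12, label="H"),
        ),
    )


_FIXTURES = {
    "water_293K": _water_293K,
    "glycine_solution": _glycine_solution,
    "collagen_glycine_solution": _collagen_glycine_solution,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> RelaxationModel:
    """Relaxation model for a named study system; see module docstring."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
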