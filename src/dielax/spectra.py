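"""Data model and file I/O for complex permittivity spectra and fit reports.

A spectrum is a set of samples of the complex permittivity
``eps* = eps' - i*eps''`` on a positive, strictly increasing frequency grid.
Files are delimited text with a header row and ``#`` comment lines; the
canonical columns are ``frequency_hz``, ``eps_real`` and ``eps_imag``, with
the loss ``eps''`` stored as a positive magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import DebyeProcess, RelaxationModel

__all__ = [
    "PermittivitySpectrum",
    "FitReport",
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_report",
    "write_report",
]

DEFAULT_COLUMNS: Mapping[str, str] = {
    "frequency": "frequency_hz",
    "eps_real": "eps_real",
    "eps_imag": "eps_imag",
}


class SpectrumFormatError(ValueError):
    """A spectrum file is structurally unreadable (e.g. a column is missing)."""


@dataclass(frozen=True)
class PermittivitySpectrum:
    """Sampled complex permittivity versus frequency.

    Parameters
    ----------
    frequency
        Frequencies in Hz, strictly increasing, all positive.
    eps_real
        Dielectric constant eps' (dimensionless).
    eps_imag
        Dielectric loss eps'' stored as a non-negative magnitude; the
        complex value is formed as ``eps' - i*eps''``.
    band_label
        Free-text band tag, e.g. ``"TDR"`` or ``"THz-TDS"``.
    temperature
        Sample temperature in K.
    """

    frequency: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    band_label: str = ""
    temperature: float = 293.0

    def __post_init__(self) -> None:
        for name in ("frequency", "eps_real", "eps_imag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if not (self.frequency.ndim == self.eps_real.ndim == self.eps_imag.ndim == 1):
            raise ValueError("spectrum arrays must be one-dimensional")
        n = self.frequency.size
        if n < 1 or self.eps_real.size != n or self.eps_imag.size != n:
            raise ValueError("frequency, eps_real, eps_imag must have equal length >= 1")
        if not np.all(np.isfinite(self.frequency)) or np.any(self.frequency <= 0):
            raise ValueError("frequencies must be finite and positive")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing (no duplicates)")
        if np.any(self.eps_imag < 0):
            raise ValueError("dielectric loss eps_imag must be non-negative")

    def __len__(self) -> int:
        return int(self.frequency.size)

    @property
    def eps_complex(self) -> np.ndarray:
        """Complex permittivity ``eps' - i*eps''``."""
        return self.eps_real - 1j * self.eps_imag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                DEFAULT_COLUMNS["frequency"]: self.frequency,
                DEFAULT_COLUMNS["eps_real"]: self.eps_real,
                DEFAULT_COLUMNS["eps_imag"]: self.eps_imag,
            }
        )


@dataclass
class FitReport:
    """Result of a relaxation-model fit.

    Residual RMS values are reported separately for the eps' and eps''
    channels, in the same (dimensionless) units as the data.
    """

    model: RelaxationModel
    residual_rms_real: float
    residual_rms_imag: float
    parameter_std_errors: dict[str, float] = field(default_factory=dict)
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        if self.residual_rms_real < 0 or self.residual_rms_imag < 0:
            raise ValueError("residual RMS values must be non-negative")
        if self.converged and not (
            np.isfinite(self.residual_rms_real) and np.isfinite(self.residual_rms_imag)
        ):
            raise ValueError("a converged report must carry finite residuals")


def read_spectrum(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    band_label: str = "",
    temperature: float = 293.0,
) -> PermittivitySpectrum:
    """Read a delimited-text spectrum file.

    ``dialect`` maps the logical names ``frequency``, ``eps_real``,
    ``eps_imag`` to the column names found in the file; by default the
    canonical names are used. Rows are sorted by frequency; duplicate
    frequencies are rejected.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", sep=None, engine="python")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise SpectrumFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SpectrumFormatError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    sub = df[[cols["frequency"], cols["eps_real"], cols["eps_imag"]]].apply(
        pd.to_numeric, errors="coerce"
    )
    if sub.isna().any().any():
        raise ValueError(f"{path}: non-numeric entries in spectrum columns")
    sub = sub.sort_values(cols["frequency"])
    return PermittivitySpectrum(
        frequency=sub[cols["frequency"]].to_numpy(),
        eps_real=sub[cols["eps_real"]].to_numpy(),
        eps_imag=sub[cols["eps_imag"]].to_numpy(),
        band_label=band_label,
        temperature=temperature,
    )


def write_spectrum(spectrum: PermittivitySpectrum, path: str | Path) -> None:
    """Write a spectrum as canonical three-column delimited text."""
    path = Path(path)
    with path.open("w") as fh:
        if spectrum.band_label:
            fh.write(f"# band: {spectrum.band_label}\n")
        fh.write(f"# temperature_K: {spectrum.temperature}\n")
        spectrum.to_frame().to_csv(fh, index=False, float_format="%.12g")


def _model_to_dict(model: RelaxationModel) -> dict:
    return {
        "eps_inf": model.eps_inf,
        "sigma_dc_S_per_m": model.sigma_dc,
        "processes": [
            {
                "label": p.label,
                "delta_eps": p.delta_eps,
                "tau_s": p.tau,
                "tau_ps": p.tau * 1e12,
                "alpha": p.alpha,
            }
            for p in model.processes
        ],
    }


def _model_from_dict(d: Mapping) -> RelaxationModel:
    procs = [
        DebyeProcess(
            delta_eps=p["delta_eps"],
            tau=p["tau_s"],
            label=p.get("label", ""),
            alpha=p.get("alpha", 0.0),
        )
        for p in d["processes"]
    ]
    return RelaxationModel(
        eps_inf=d["eps_inf"], processes=procs, sigma_dc=d.get("sigma_dc_S_per_m", 0.0)
    )


def write_report(report: FitReport, path: str | Path) -> None:
    """Serialize a fit report to JSON.

    Relaxation times are stored in SI seconds, with a picosecond
    convenience field alongside; ``read_report(write_report(x)) == x``.
    """
    payload = {
        "model": _model_to_dict(report.model),
        "residual_rms_real": report.residual_rms_real,
        "residual_rms_imag": report.residual_rms_imag,
        "parameter_std_errors": report.parameter_std_errors,
        "n_iterations": report.n_iterations,
        "converged": report.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | Path) -> FitReport:
    """Inverse of :func:`write_report`."""
    d = json.loads(Path(path).read_text())
    return FitReport(
        model=_model_from_dict(d["model"]),
        residual_rms_real=d["residual_rms_real"],
        residual_rms_imag=d["residual_rms_imag"],
        parameter_std_errors=dict(d.get("parameter_std_errors", {})),
        n_iterations=d.get("n_iterations", 0),
        converged=d.get("converged", False),
    )
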