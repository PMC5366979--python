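"""Nonlinear least-squares decomposition of permittivity spectra.

A spectrum is decomposed into eps_inf plus N Debye processes (optionally
plus a dc-conductivity loss term) by minimizing the joint residual over the
eps' and eps'' channels simultaneously. Relaxation times and strengths are
optimized in log10 space, which enforces positivity by construction and
conditions the problem across the decades the parameters span. A small
number of seeded multi-start perturbations guards against local minima.

After fitting, processes are relabelled in descending relaxation time using
the L/M/H convention (low-, intermediate-, high-frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .models import DebyeProcess, RelaxationModel, evaluate_model
from .spectra import FitReport, PermittivitySpectrum

__all__ = ["FitConfig", "initial_guess", "fit_relaxation", "compare_models"]

_MAX_PROCESSES = 4

#: labels assigned to fitted processes in descending tau, per process count
_LABEL_SETS = {1: ("L",), 2: ("L", "H"), 3: ("L", "M", "H"), 4: ("L", "M1", "M2", "H")}

# auto-conductivity heuristic: refit with a dc term when the mean relative
# excess loss over the lowest _DC_N_POINTS frequencies exceeds _DC_EXCESS
_DC_N_POINTS = 3
_DC_EXCESS = 0.05


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_relaxation`.

    ``tau_bounds`` optionally pins each process (descending tau order) to a
    (lo, hi) interval in seconds; by default bounds extend 1.5 decades
    beyond the band-implied range [1/(2 pi f_max), 1/(2 pi f_min)].
    ``fit_conductivity`` may be True, False or "auto" (heuristic detection
    of low-frequency excess loss).
    """

    n_processes: int = 3
    weight_mode: str = "relative"
    tau_bounds: tuple[tuple[float, float], ...] | None = None
    max_iterations: int = 5000
    tolerance: float = 1e-12
    seed: int = 0
    n_starts: int = 5
    fit_conductivity: bool | str = False

    def __post_init__(self) -> None:
        if not 1 <= self.n_processes <= _MAX_PROCESSES:
            raise ValueError(f"n_processes must be in 1..{_MAX_PROCESSES}")
        if self.weight_mode not in ("uniform", "relative"):
            raise ValueError("weight_mode must be 'uniform' or 'relative'")
        if self.tau_bounds is not None:
            if len(self.tau_bounds) != self.n_processes:
                raise ValueError("tau_bounds must give one interval per process")
            flat = sorted(self.tau_bounds, key=lambda iv: -iv[0])
            for lo, hi in flat:
                if not 0 < lo < hi:
                    raise ValueError("tau bounds must satisfy 0 < lo < hi")
            for (lo1, _), (_, hi2) in zip(flat[:-1], flat[1:]):
                if hi2 > lo1:
                    raise ValueError("tau_bounds intervals must not overlap")
        if self.fit_conductivity not in (True, False, "auto"):
            raise ValueError("fit_conductivity must be True, False or 'auto'")


def _band_tau_range(spectrum: PermittivitySpectrum) -> tuple[float, float]:
    f = spectrum.frequency
    return 1.0 / (2.0 * np.pi * f[-1]), 1.0 / (2.0 * np.pi * f[0])


def initial_guess(spectrum: PermittivitySpectrum, n_processes: int) -> RelaxationModel:
    """Seed model for the optimizer.

    Relaxation times are log-spaced across the band-implied interval
    [1/(2 pi f_max), 1/(2 pi f_min)], strengths split the observed eps'
    span equally, and eps_inf is seeded from the highest-frequency eps'.
    A spectrum with no eps' dispersion is rejected as degenerate.
    """
    if not 1 <= n_processes <= _MAX_PROCESSES:
        raise ValueError(f"n_processes must be in 1..{_MAX_PROCESSES}")
    f = spectrum.frequency
    if f[-1] / f[0] < 10.0:
        raise ValueError("spectrum must span at least one decade of frequency")
    span = float(spectrum.eps_real[0] - spectrum.eps_real[-1])
    if span <= 0:
        raise ValueError("degenerate spectrum: no eps' dispersion to decompose")
    t_lo, t_hi = _band_tau_range(spectrum)
    taus = np.geomspace(t_lo, t_hi, n_processes + 2)[1:-1][::-1]  # descending
    labels = _LABEL_SETS[n_processes]
    procs = tuple(
        DebyeProcess(delta_eps=span / n_processes, tau=float(t), label=lab)
        for t, lab in zip(taus, labels)
    )
    eps_inf = max(float(spectrum.eps_real[-1]), 1.0)
    return RelaxationModel(eps_inf=eps_inf, processes=procs)


def _params_from_model(
    model: RelaxationModel,
    tau_bounds: list[tuple[float, float]],
    with_sigma: bool,
) -> lmfit.Parameters:
    params = lmfit.Parameters()
    params.add("eps_inf", value=model.eps_inf, min=1.0)
    for i, p in enumerate(model.processes):
        lo, hi = tau_bounds[i]
        params.add(
            f"lg_tau_{i}",
            value=np.clip(math.log10(p.tau), math.log10(lo), math.log10(hi)),
            min=math.log10(lo),
            max=math.log10(hi),
        )
        params.add(f"lg_deps_{i}", value=math.log10(p.delta_eps), min=-4.0, max=4.0)
    if with_sigma:
        sigma0 = model.sigma_dc if model.sigma_dc > 0 else 1e-3
        params.add("lg_sigma", value=math.log10(sigma0), min=-8.0, max=2.0)
    return params


def _model_from_params(params, n_processes: int, with_sigma: bool) -> RelaxationModel:
    procs = tuple(
        DebyeProcess(
            delta_eps=10.0 ** params[f"lg_deps_{i}"].value,
            tau=10.0 ** params[f"lg_tau_{i}"].value,
            label=f"p{i}",
        )
        for i in range(n_processes)
    )
    sigma = 10.0 ** params["lg_sigma"].value if with_sigma else 0.0
    return RelaxationModel(eps_inf=params["eps_inf"].value, processes=procs, sigma_dc=sigma)


def _weights(spectrum: PermittivitySpectrum, mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "uniform":
        one = np.ones_like(spectrum.frequency)
        return one, one
    # relative: divide by |data|, floored at 1 so near-zero loss cannot
    # dominate the objective
    w_re = 1.0 / np.maximum(np.abs(spectrum.eps_real), 1.0)
    w_im = 1.0 / np.maximum(np.abs(spectrum.eps_imag), 1.0)
    return w_re, w_im


def _residual(params, spectrum, n_processes, with_sigma, w_re, w_im):
    model = _model_from_params(params, n_processes, with_sigma)
    pred = evaluate_model(model, spectrum.frequency)
    return np.concatenate(
        [
            (pred.eps_real - spectrum.eps_real) * w_re,
            (pred.eps_imag - spectrum.eps_imag) * w_im,
        ]
    )


def _relabel(model: RelaxationModel) -> RelaxationModel:
    labels = _LABEL_SETS[len(model.processes)]
    procs = tuple(
        replace(p, label=lab) for p, lab in zip(model.processes, labels)
    )  # model.processes already sorted descending tau
    return RelaxationModel(eps_inf=model.eps_inf, processes=procs, sigma_dc=model.sigma_dc)


def _fit_once(spectrum, config, start_model, with_sigma, tau_bounds):
    import warnings

    w_re, w_im = _weights(spectrum, config.weight_mode)
    params = _params_from_model(start_model, tau_bounds, with_sigma)
    with warnings.catch_warnings():
        # degenerate fits can yield an indefinite covariance; lmfit then
        # reports nan stderr, which is what we want, minus the noise
        warnings.simplefilter("ignore", RuntimeWarning)
        result = lmfit.minimize(
        _residual,
        params,
        args=(spectrum, config.n_processes, with_sigma, w_re, w_im),
        method="least_squares",
        max_nfev=config.max_iterations,
        xtol=config.tolerance,
        ftol=config.tolerance,
        gtol=config.tolerance,
    )
    return result


def _report_from_result(result, spectrum, config, with_sigma) -> FitReport:
    model = _relabel(_model_from_params(result.params, config.n_processes, with_sigma))
    pred = evaluate_model(model, spectrum.frequency)
    rms_re = float(np.sqrt(np.mean((pred.eps_real - spectrum.eps_real) ** 2)))
    rms_im = float(np.sqrt(np.mean((pred.eps_imag - spectrum.eps_imag) ** 2)))
    # std errors mapped out of log10 space: s(tau) ~ tau * ln(10) * s(lg_tau)
    errors: dict[str, float] = {}
    ln10 = math.log(10.0)
    for i, proc in enumerate(model.processes):
        lab = proc.label
        st = result.params[f"lg_tau_{i}"].stderr
        sd = result.params[f"lg_deps_{i}"].stderr
        errors[f"tau_{lab}"] = proc.tau * ln10 * st if st is not None else float("nan")
        errors[f"delta_eps_{lab}"] = (
            proc.delta_eps * ln10 * sd if sd is not None else float("nan")
        )
    se = result.params["eps_inf"].stderr
    errors["eps_inf"] = se if se is not None else float("nan")
    if with_sigma:
        ss = result.params["lg_sigma"].stderr
        errors["sigma_dc"] = (
            model.sigma_dc * ln10 * ss if ss is not None else float("nan")
        )
    return FitReport(
        model=model,
        residual_rms_real=rms_re,
        residual_rms_imag=rms_im,
        parameter_std_errors=errors,
        n_iterations=int(result.nfev),
        converged=bool(result.success),
    )


def _fit_multistart(spectrum, config, initial, with_sigma) -> FitReport:
    n = config.n_processes
    if config.tau_bounds is not None:
        tau_bounds = sorted(config.tau_bounds, key=lambda iv: -iv[0])
    else:
        t_lo, t_hi = _band_tau_range(spectrum)
        tau_bounds = [(t_lo / 10**1.5, t_hi * 10**1.5)] * n
    start = initial if initial is not None else initial_guess(spectrum, n)
    rng = np.random.default_rng(config.seed)
    best = None
    for k in range(max(config.n_starts, 1)):
        if k == 0:
            model_k = start
        else:
            procs = tuple(
                replace(
                    p,
                    tau=p.tau * 10 ** rng.normal(0.0, 0.3),
                    delta_eps=p.delta_eps * 10 ** rng.normal(0.0, 0.2),
                )
                for p in start.processes
            )
            model_k = RelaxationModel(
                eps_inf=start.eps_inf, processes=procs, sigma_dc=start.sigma_dc
            )
        result = _fit_once(spectrum, config, model_k, with_sigma, tau_bounds)
        cost = float(np.sum(result.residual**2))
        if best is None or (result.success and cost < best[0]):
            best = (cost, result)
    return _report_from_result(best[1], spectrum, config, with_sigma)


def fit_relaxation(
    spectrum: PermittivitySpectrum,
    config: FitConfig | None = None,
    initial: RelaxationModel | None = None,
) -> FitReport:
    """Fit eps_inf + N Debye processes to a spectrum.

    The joint residual over eps' and eps'' is minimized simultaneously,
    with per-channel relative weighting by default. Non-convergence is
    reported via ``converged=False``, never as an unflagged partial answer.
    Passing ``initial`` restarts from a previous solution (refitting a
    returned model is a fixed point up to the convergence tolerance).
    """
    config = config or FitConfig()
    n_free = 2 * config.n_processes + 1 + (1 if config.fit_conductivity is True else 0)
    if len(spectrum) < 2 * n_free:
        raise ValueError(
            f"need >= {2 * n_free} points to fit {n_free} free parameters"
        )
    if config.fit_conductivity is True:
        return _fit_multistart(spectrum, config, initial, with_sigma=True)
    report = _fit_multistart(spectrum, config, initial, with_sigma=False)
    if config.fit_conductivity == "auto":
        pred = evaluate_model(report.model, spectrum.frequency)
        lo = slice(0, _DC_N_POINTS)
        excess = np.mean(
            (spectrum.eps_imag[lo] - pred.eps_imag[lo])
            / np.maximum(spectrum.eps_imag[lo], 1e-12)
        )
        if excess > _DC_EXCESS:
            with_dc = _fit_multistart(spectrum, config, initial, with_sigma=True)
            if with_dc.converged and _criterion(with_dc, spectrum) < _criterion(
                report, spectrum
            ):
                return with_dc
    return report


def _n_free(report: FitReport) -> int:
    return 2 * len(report.model.processes) + 1 + (1 if report.model.sigma_dc > 0 else 0)


def _criterion(report: FitReport, spectrum: PermittivitySpectrum) -> float:
    """Penalized-residual ranking criterion (smaller is better).

    AIC-like: N ln(chi2/N) + 2k over the relative-weighted joint residual,
    with k the number of free parameters. Computed with a fixed relative
    weighting so reports fitted under different weight modes rank on a
    common scale. The per-point chi2 is floored at (1e-8)^2: residuals at
    the level of optimizer round-off are treated as exact, so two
    numerically perfect fits rank by parameter count alone.
    """
    w_re, w_im = _weights(spectrum, "relative")
    pred = evaluate_model(report.model, spectrum.frequency)
    res = np.concatenate(
        [
            (pred.eps_real - spectrum.eps_real) * w_re,
            (pred.eps_imag - spectrum.eps_imag) * w_im,
        ]
    )
    n = res.size
    chi2 = max(float(np.sum(res**2)), n * 1e-16)
    return n * math.log(chi2 / n) + 2.0 * _n_free(report)


def compare_models(
    spectrum: PermittivitySpectrum, configs: list[FitConfig]
) -> list[tuple[FitConfig, FitReport, float]]:
    """Fit each config and rank converged fits by the penalized criterion.

    Returns (config, report, criterion) triples, best first; non-converged
    fits are appended after the ranked ones with criterion = inf. The
    ranking is deterministic for identical inputs.
    """
    if len(configs) < 2:
        raise ValueError("compare_models needs at least 2 configs")
    fitted = [(cfg, fit_relaxation(spectrum, cfg)) for cfg in configs]
    ranked = [
        (cfg, rep, _criterion(rep, spectrum)) for cfg, rep in fitted if rep.converged
    ]
    ranked.sort(key=lambda t: t[2])
    failed = [(cfg, rep, float("inf")) for cfg, rep in fitted if not rep.converged]
    return ranked + failed
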