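"""Spectral decomposition: seeds, round-trips, model ranking, dc detection."""

import numpy as np
import pytest

import dielax as dx


def _noiseless(model, band=None):
    return dx.simulate_spectrum(model, band or dx.TDR_BAND, dx.NoiseSpec(0.0))


class TestInitialGuess:
    def test_single_process_seed_brackets_truth(self, water_model):
        spec = _noiseless(water_model)
        guess = dx.initial_guess(spec, 1)
        true_tau = water_model.processes[0].tau
        assert true_tau / 10 < guess.processes[0].tau < true_tau * 10

    def test_three_seeds_distinct_and_descending(self, glycine_model):
        guess = dx.initial_guess(_noiseless(glycine_model), 3)
        taus = [p.tau for p in guess.processes]
        assert len(set(taus)) == 3
        assert taus == sorted(taus, reverse=True)

    def test_flat_spectrum_is_degenerate(self):
        spec = dx.PermittivitySpectrum(
            frequency=np.geomspace(1e9, 1e11, 20),
            eps_real=np.full(20, 5.0),
            eps_imag=np.zeros(20),
        )
        with pytest.raises(ValueError, match="degenerate"):
            dx.initial_guess(spec, 1)

    def test_narrow_band_rejected(self):
        spec = dx.PermittivitySpectrum(
            frequency=np.linspace(1e9, 2e9, 20),
            eps_real=np.linspace(70, 60, 20),
            eps_imag=np.full(20, 10.0),
        )
        with pytest.raises(ValueError, match="decade"):
            dx.initial_guess(spec, 1)


class TestFitRelaxation:
    def test_noiseless_three_process_round_trip(self, glycine_model):
        """All generator parameters recovered to 0.1% from a clean spectrum."""
        report = dx.fit_relaxation(_noiseless(glycine_model))
        assert report.converged
        for fitted, true in zip(report.model.processes, glycine_model.processes):
            assert fitted.tau == pytest.approx(true.tau, rel=1e-3)
            assert fitted.delta_eps == pytest.approx(true.delta_eps, rel=1e-3)
        assert report.model.eps_inf == pytest.approx(glycine_model.eps_inf, rel=1e-3)

    def test_single_process_static_permittivity_recovery(self, water_model):
        report = dx.fit_relaxation(
            _noiseless(water_model), dx.FitConfig(n_processes=1)
        )
        assert dx.static_permittivity(report.model) == pytest.approx(
            dx.static_permittivity(water_model), rel=5e-3
        )

    def test_labels_follow_descending_tau(self, glycine_model):
        report = dx.fit_relaxation(_noiseless(glycine_model))
        assert [p.label for p in report.model.processes] == ["L", "M", "H"]

    def test_refit_from_solution_is_fixed_point(self, glycine_model):
        first = dx.fit_relaxation(_noiseless(glycine_model))
        second = dx.fit_relaxation(_noiseless(glycine_model), initial=first.model)
        for p1, p2 in zip(first.model.processes, second.model.processes):
            assert p2.tau == pytest.approx(p1.tau, rel=1e-6)
            assert p2.delta_eps == pytest.approx(p1.delta_eps, rel=1e-6)

    def test_fitted_parameters_strictly_positive_under_noise(self, glycine_model):
        spec = dx.simulate_spectrum(glycine_model, dx.TDR_BAND, dx.NoiseSpec(0.1, 3))
        report = dx.fit_relaxation(spec)
        for p in report.model.processes:
            assert p.tau > 0 and p.delta_eps > 0

    def test_too_few_points_rejected(self, water_model):
        spec = _noiseless(water_model, dx.BandSpec(5e8, 2.5e10, points_per_decade=3))
        with pytest.raises(ValueError, match="points"):
            dx.fit_relaxation(spec, dx.FitConfig(n_processes=3))

    def test_auto_conductivity_detects_contaminated_loss(self, water_model):
        dirty = dx.RelaxationModel(
            water_model.eps_inf, water_model.processes, sigma_dc=0.08
        )
        spec = _noiseless(dirty)
        report = dx.fit_relaxation(
            spec, dx.FitConfig(n_processes=1, fit_conductivity="auto")
        )
        assert report.model.sigma_dc == pytest.approx(0.08, rel=0.05)
        clean_report = dx.fit_relaxation(
            _noiseless(water_model), dx.FitConfig(n_processes=1, fit_conductivity="auto")
        )
        assert clean_report.model.sigma_dc == 0.0

    def test_explicit_conductivity_cofit(self, water_model):
        dirty = dx.RelaxationModel(
            water_model.eps_inf, water_model.processes, sigma_dc=0.05
        )
        report = dx.fit_relaxation(
            _noiseless(dirty), dx.FitConfig(n_processes=1, fit_conductivity=True)
        )
        assert report.model.sigma_dc == pytest.approx(0.05, rel=0.05)
        assert report.model.processes[0].tau == pytest.approx(9.4e-12, rel=1e-3)


class TestCompareModels:
    def test_three_process_data_prefers_three_processes(self, glycine_model):
        ranked = dx.compare_models(
            _noiseless(glycine_model),
            [dx.FitConfig(n_processes=2), dx.FitConfig(n_processes=3)],
        )
        assert len(ranked[0][1].model.processes) == 3

    def test_one_process_data_prefers_parsimony(self, water_model):
        ranked = dx.compare_models(
            _noiseless(water_model),
            [dx.FitConfig(n_processes=1), dx.FitConfig(n_processes=3)],
        )
        assert len(ranked[0][1].model.processes) == 1

    def test_identical_configs_rank_stably(self, water_model):
        spec = dx.simulate_spectrum(water_model, dx.TDR_BAND, dx.NoiseSpec(0.03, 2))
        cfg = dx.FitConfig(n_processes=1)
        ranked = dx.compare_models(spec, [cfg, cfg])
        assert ranked[0][2] == ranked[1][2]
        assert ranked[0][1].model == ranked[1][1].model

    def test_requires_at_least_two_configs(self, water_model):
        with pytest.raises(ValueError):
            dx.compare_models(_noiseless(water_model), [dx.FitConfig()])


class TestFitConfigValidation:
    def test_overlapping_tau_bounds_rejected(self):
        with pytest.raises(ValueError):
            dx.FitConfig(
                n_processes=2, tau_bounds=((1e-11, 1e-9), (5e-10, 1e-8))
            )

    def test_process_count_bounds(self):
        with pytest.raises(ValueError):
            dx.FitConfig(n_processes=0)
        with pytest.raises(ValueError):
            dx.FitConfig(n_processes=5)
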