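"""Forward Debye model: closed-form values, limits and shape invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dielax as dx
from dielax.constants import EPSILON_0

process_strategy = st.builds(
    dx.DebyeProcess,
    delta_eps=st.floats(0.1, 200.0),
    tau=st.floats(1e-13, 1e-9),
)


class TestDebyeTerm:
    @pytest.mark.parametrize(
        "delta_eps, tau, freq, expected",
        [
            # zero-frequency limit: the full strength, no loss
            (28.7, 72e-12, 0.0, 28.7 + 0j),
            # omega*tau = 1: half strength in each channel
            (28.7, 72e-12, 1.0 / (2 * np.pi * 72e-12), 14.35 - 14.35j),
            # direct complex arithmetic at omega*tau = 0.45239
            (75.2, 72e-12, 1e9, 62.4215 - 28.2398j),
        ],
    )
    def test_closed_form_values(self, delta_eps, tau, freq, expected):
        value = dx.debye_term(dx.DebyeProcess(delta_eps, tau), freq)
        assert value == pytest.approx(expected, rel=1e-4)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            dx.debye_term(dx.DebyeProcess(1.0, 1e-11), -1e9)

    @given(process=process_strategy)
    def test_loss_peaks_at_inverse_tau_with_half_strength(self, process):
        f_peak = 1.0 / (2 * np.pi * process.tau)
        at_peak = dx.debye_term(process, f_peak)
        assert -at_peak.imag == pytest.approx(process.delta_eps / 2, rel=1e-12)
        # the peak is a maximum: loss is lower a factor 2 away in frequency
        for f in (f_peak / 2, f_peak * 2):
            assert -dx.debye_term(process, f).imag < -at_peak.imag

    def test_cole_cole_broadens_below_debye_peak(self):
        debye = dx.DebyeProcess(20.0, 50e-12)
        broad = dx.DebyeProcess(20.0, 50e-12, alpha=0.2)
        f_peak = 1.0 / (2 * np.pi * 50e-12)
        assert -dx.debye_term(broad, f_peak).imag < -dx.debye_term(debye, f_peak).imag


class TestEvaluateModel:
    def test_empty_model_is_flat(self):
        model = dx.RelaxationModel(eps_inf=5.3)
        spec = dx.evaluate_model(model, np.geomspace(1e9, 1e12, 20))
        assert np.allclose(spec.eps_real, 5.3)
        assert np.allclose(spec.eps_imag, 0.0)

    def test_additivity_of_processes(self):
        p1 = dx.DebyeProcess(30.0, 70e-12, "L")
        p2 = dx.DebyeProcess(70.0, 9e-12, "H")
        f = np.geomspace(5e8, 2.5e10, 30)
        both = dx.evaluate_model(dx.RelaxationModel(5.0, (p1, p2)), f)
        one = dx.evaluate_model(dx.RelaxationModel(5.0, (p1,)), f)
        two = dx.evaluate_model(dx.RelaxationModel(5.0, (p2,)), f)
        assert np.allclose(both.eps_real, one.eps_real + two.eps_real - 5.0)
        assert np.allclose(both.eps_imag, one.eps_imag + two.eps_imag)

    def test_single_process_peak_values(self):
        model = dx.RelaxationModel(5.0, (dx.DebyeProcess(75.2, 9.4e-12),))
        f_peak = 1.0 / (2 * np.pi * 9.4e-12)  # 16.93 GHz
        spec = dx.evaluate_model(model, [f_peak])
        assert spec.eps_real[0] == pytest.approx(5.0 + 75.2 / 2, rel=1e-12)
        assert spec.eps_imag[0] == pytest.approx(75.2 / 2, rel=1e-12)

    def test_dc_conductivity_adds_inverse_frequency_loss(self):
        clean = dx.RelaxationModel(5.0, (dx.DebyeProcess(75.0, 9.4e-12),))
        dirty = dx.RelaxationModel(5.0, clean.processes, sigma_dc=0.05)
        f = np.array([5e8, 1e9])
        excess = (
            dx.evaluate_model(dirty, f).eps_imag - dx.evaluate_model(clean, f).eps_imag
        )
        assert np.allclose(excess, 0.05 / (2 * np.pi * f * EPSILON_0))
        # real channel untouched
        assert np.allclose(
            dx.evaluate_model(dirty, f).eps_real, dx.evaluate_model(clean, f).eps_real
        )

    def test_dc_term_rejects_zero_frequency(self):
        model = dx.RelaxationModel(5.0, sigma_dc=0.1)
        with pytest.raises(ValueError):
            dx.evaluate_model(model, [0.0, 1e9])

    @given(
        eps_inf=st.floats(1.0, 10.0),
        processes=st.lists(process_strategy, min_size=0, max_size=3),
    )
    def test_eps_real_monotone_and_loss_nonnegative(self, eps_inf, processes):
        """Without conductivity, eps' never increases with f and eps'' >= 0."""
        model = dx.RelaxationModel(eps_inf, tuple(processes))
        spec = dx.evaluate_model(model, np.geomspace(1e8, 1e13, 60))
        assert np.all(np.diff(spec.eps_real) <= 1e-12)
        assert np.all(spec.eps_imag >= 0)

    @given(processes=st.lists(process_strategy, min_size=1, max_size=3))
    def test_low_frequency_limit_is_static_permittivity(self, processes):
        model = dx.RelaxationModel(3.0, tuple(processes))
        tau_max = max(p.tau for p in model.processes)
        f_low = 1e-4 / (2 * np.pi * tau_max)
        spec = dx.evaluate_model(model, [f_low])
        assert spec.eps_real[0] == pytest.approx(dx.static_permittivity(model), rel=1e-6)


class TestStaticPermittivity:
    def test_glycine_solution_value(self):
        model = dx.RelaxationModel(91.3, (dx.DebyeProcess(28.7, 72e-12, "L"),))
        assert dx.static_permittivity(model) == pytest.approx(120.0)

    def test_empty_and_multi_process_sums(self):
        assert dx.static_permittivity(dx.RelaxationModel(5.3)) == 5.3
        model = dx.RelaxationModel(
            5.0, (dx.DebyeProcess(75.0, 1e-11, "a"), dx.DebyeProcess(10.0, 1e-10, "b"))
        )
        assert dx.static_permittivity(model) == pytest.approx(90.0)


class TestModelInvariants:
    def test_processes_sorted_descending_tau(self):
        model = dx.RelaxationModel(
            5.0,
            (dx.DebyeProcess(1.0, 1e-12, "H"), dx.DebyeProcess(1.0, 1e-10, "L")),
        )
        taus = [p.tau for p in model.processes]
        assert taus == sorted(taus, reverse=True)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            dx.DebyeProcess(-1.0, 1e-11)
        with pytest.raises(ValueError):
            dx.DebyeProcess(1.0, 0.0)
        with pytest.raises(ValueError):
            dx.RelaxationModel(eps_inf=0.5)
        with pytest.raises(ValueError):
            dx.RelaxationModel(
                5.0,
                (dx.DebyeProcess(1.0, 1e-12, "L"), dx.DebyeProcess(1.0, 1e-10, "L")),
            )
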