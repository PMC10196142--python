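"""Closed-form deposition probabilities against independent evaluation."""

import numpy as np
import pytest

from stochlung import physics
from stochlung.physics import (ParticleTransportProperties, combine_mechanisms,
                               cunningham, diffusion_coefficient,
                               extrathoracic_efficiency, p_diffusion,
                               p_impaction, p_sedimentation,
                               settling_velocity)

MU = 1.81e-5
LAM = 0.066
KB = 1.380649e-23
T = 310.0


class TestTransportProperties:
    def test_slip_vanishes_for_large_particles(self):
        assert cunningham(1e4) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("d_um", [0.1, 0.5, 1.0, 3.0, 10.0])
    def test_cunningham_matches_direct_formula(self, d_um):
        expected = 1.0 + (LAM / d_um) * (2.514 + 0.8 * np.exp(-0.55 * d_um / LAM))
        assert cunningham(d_um) == pytest.approx(expected, rel=1e-12)

    def test_cunningham_reference_values(self):
        assert cunningham(1.0) == pytest.approx(1.1659, abs=2e-4)
        assert cunningham(10.0) == pytest.approx(1.0166, abs=2e-4)

    @pytest.mark.parametrize("d_um, expected", [
        (1.0, 3.511e-5), (3.0, 2.860e-4)])
    def test_settling_velocity_aerodynamic(self, d_um, expected):
        assert settling_velocity(d_um) == pytest.approx(expected, rel=2e-3)

    def test_settling_zero_diameter(self):
        assert settling_velocity(0.0) == 0.0

    def test_diffusion_monotone_decreasing_and_values(self):
        d = np.array([0.1, 0.5, 1.0, 5.0])
        dd = diffusion_coefficient(d)
        assert np.all(np.diff(dd) < 0)
        # direct Stokes-Einstein evaluation
        cc1 = cunningham(1.0)
        assert diffusion_coefficient(1.0) == pytest.approx(
            KB * T * cc1 / (3 * np.pi * MU * 1e-6), rel=1e-12)
        assert diffusion_coefficient(1.0) == pytest.approx(2.93e-11, rel=5e-3)
        assert cunningham(0.1) == pytest.approx(2.889, abs=2e-3)
        assert diffusion_coefficient(0.1) == pytest.approx(7.25e-10, rel=5e-3)

    def test_particle_properties_dataclass(self):
        p = ParticleTransportProperties.from_diameter(1.0)
        assert p.cc >= 1.0 and p.v_s > 0 and p.d_diff > 0
        assert p.stokes(1.0, 0.2) > 0


class TestMechanismProbabilities:
    def test_impaction_zero_stokes(self):
        assert p_impaction(0.0, 30.0) == 0.0

    def test_impaction_saturates(self):
        assert p_impaction(5.0, 60.0) == 1.0

    def test_impaction_matches_independent_evaluation(self):
        # independent re-coding of the arccos closed form
        theta = np.deg2rad(30.0)
        st = 0.5
        x = theta * st
        expected = 1 - (2 / np.pi) * np.arccos(x) - (1 / np.pi) * np.sin(2 * np.arccos(x))
        assert p_impaction(0.5, 30.0) == pytest.approx(expected, rel=1e-12)
        assert 0.0 < expected < 1.0

    def test_impaction_monotone_in_stokes(self):
        st = np.linspace(0.0, 2.0, 50)
        p = p_impaction(st, 45.0)
        assert np.all(np.diff(p) >= 0)

    def test_sedimentation_limits_and_value(self):
        assert p_sedimentation(3.5e-5, 1.0, 0.0, 0.2) == 0.0
        assert p_sedimentation(3.5e-5, 0.0, 10.0, 0.2) == 0.0
        expected = 1 - np.exp(-4 * 3.5e-5 * 1.0 / (np.pi * 0.002))
        assert expected == pytest.approx(0.0220, abs=2e-4)
        assert p_sedimentation(3.5e-5, 1.0, 1.0, 0.2) == pytest.approx(expected, rel=1e-12)

    def test_diffusion_limits_and_value(self):
        assert p_diffusion(2.9e-11, 0.0, 1e-3) == 0.0
        assert p_diffusion(0.0, 5.0, 1e-3) == 0.0
        assert p_diffusion(2.9e-11, 1.0, 1e-3) == pytest.approx(1.68e-4, rel=2e-3)

    @pytest.mark.parametrize("pi, ps, pd_, expected", [
        (0.0, 0.0, 0.0, 0.0),
        (1.0, 0.2, 0.3, 1.0),
        (0.1, 0.2, 0.3, 0.496),
    ])
    def test_combination_rule(self, pi, ps, pd_, expected):
        assert combine_mechanisms(pi, ps, pd_) == pytest.approx(expected, rel=1e-12)

    def test_probabilities_stay_in_unit_interval(self):
        rng = np.random.default_rng(0)
        st = rng.uniform(0, 10, 200)
        theta = rng.uniform(0, 90, 200)
        p = p_impaction(st, theta)
        assert np.all((p >= 0) & (p <= 1))
        ps = p_sedimentation(rng.uniform(0, 1e-2, 200), rng.uniform(-1, 1, 200),
                             rng.uniform(0, 100, 200), rng.uniform(0.01, 2, 200))
        assert np.all((ps >= 0) & (ps <= 1))


class TestExtrathoracic:
    def test_small_particle_limit_is_diffusive_only(self):
        # impaction vanishes with d^2 Q; what remains is the diffusive term
        eta = extrathoracic_efficiency(0.01, 30.0)
        eta_diff_only = extrathoracic_efficiency(0.01, 30.0, a=1e-30)
        assert eta == pytest.approx(eta_diff_only, abs=1e-6)
        assert eta < 0.10

    def test_monotone_in_impaction_parameter(self):
        assert extrathoracic_efficiency(5.0, 60.0) > extrathoracic_efficiency(1.0, 30.0)
        d2q = np.array([10, 100, 1000, 5000], dtype=float)
        etas = [float(extrathoracic_efficiency(np.sqrt(x / 60.0), 60.0)) for x in d2q]
        assert np.all(np.diff(etas) > 0)

    def test_default_impaction_term_value(self):
        # d=5 um, Q=60 L/min: 1 - exp(-1.1e-4 * 1500**1.4) = 0.9539
        expected_imp = 1 - np.exp(-1.1e-4 * (25.0 * 60.0) ** 1.4)
        assert expected_imp == pytest.approx(0.9539, abs=5e-4)
        eta = extrathoracic_efficiency(5.0, 60.0)
        assert eta >= expected_imp
        assert eta == pytest.approx(expected_imp, abs=5e-3)

    def test_calibration_anchor_small_particle(self):
        assert extrathoracic_efficiency(1.0, 30.0) < 0.10

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            extrathoracic_efficiency(-1.0, 30.0)
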