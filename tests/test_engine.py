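"""Monte Carlo deposition engine: conservation, limits, determinism."""

import numpy as np
import pandas as pd
import pytest

from stochlung.aerosol import AerosolSpec, device_preset
from stochlung.cohort import CohortConfig, generate_cohort
from stochlung.engine import (DepositionResult, mean_of_two, row_seed,
                              run_cohort, simulate_deposition,
                              single_tube_harness)

N_SMALL = 4000


class TestSimulateDeposition:
    def test_mass_conservation(self, control_lungs, control_pmdi_maneuver,
                               pmdi_spec):
        r = simulate_deposition(control_lungs, control_pmdi_maneuver,
                                pmdi_spec, N_SMALL, seed=1)
        assert r.pd_pct + r.etd_pct + r.exhaled_pct == pytest.approx(100.0, abs=1e-9)
        assert r.per_generation.sum() == pytest.approx(r.pd_pct, abs=1e-9)
        assert np.all(r.per_generation >= 0)

    def test_giant_particles_stop_in_the_throat(self, control_lungs,
                                                control_pmdi_maneuver):
        spec = AerosolSpec(mmad=100.0, gsd=1.2, emission_window=(0.0, 0.3),
                           et_coeff=8e-3)
        r = simulate_deposition(control_lungs, control_pmdi_maneuver, spec,
                                20_000, seed=2)
        assert r.etd_pct > 99.0

    def test_endless_breath_hold_leaves_nothing_to_exhale(
            self, control_lungs, pmdi_spec, control_pmdi_maneuver):
        m = control_pmdi_maneuver
        from stochlung.maneuver import Maneuver
        long_bh = Maneuver(ivc_d=m.ivc_d, pif_d=m.pif_d, t_in=m.t_in,
                           t_bh=1e4, device=m.device)
        r = simulate_deposition(control_lungs, long_bh, pmdi_spec,
                                20_000, seed=3)
        assert r.exhaled_pct < 1.0

    def test_reported_standard_errors(self, control_lungs,
                                      control_pmdi_maneuver, pmdi_spec):
        r = simulate_deposition(control_lungs, control_pmdi_maneuver,
                                pmdi_spec, N_SMALL, seed=4)
        p = r.pd_pct / 100.0
        assert r.se_pd == pytest.approx(
            np.sqrt(p * (1 - p) / N_SMALL) * 100.0, rel=1e-9)

    def test_seed_determinism(self, control_lungs, control_pmdi_maneuver,
                              pmdi_spec):
        r1 = simulate_deposition(control_lungs, control_pmdi_maneuver,
                                 pmdi_spec, 2000, seed=11)
        r2 = simulate_deposition(control_lungs, control_pmdi_maneuver,
                                 pmdi_spec, 2000, seed=11)
        assert r1.pd_pct == r2.pd_pct and r1.etd_pct == r2.etd_pct
        assert np.array_equal(r1.per_generation, r2.per_generation)

    def test_se_scales_with_sqrt_n(self, control_lungs, control_pmdi_maneuver,
                                   pmdi_spec):
        r_big = simulate_deposition(control_lungs, control_pmdi_maneuver,
                                    pmdi_spec, 16_000, seed=5)
        r_small = simulate_deposition(control_lungs, control_pmdi_maneuver,
                                      pmdi_spec, 4_000, seed=6)
        assert r_small.se_pd / r_big.se_pd == pytest.approx(2.0, rel=0.1)

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            DepositionResult(pd_pct=50.0, etd_pct=30.0, exhaled_pct=30.0,
                             se_pd=0.1, se_etd=0.1,
                             per_generation=np.zeros(26),
                             n_particles=10, seed=0)


class TestSingleTubeOracle:
    def test_monte_carlo_matches_closed_form(self):
        """Bernoulli tallies converge to the combined closed form."""
        frac, se, p = single_tube_harness(
            d_airway_cm=0.2, length_cm=1.0, branch_deg=35.0, cos_gravity=0.8,
            d_p_um=3.0, flow_lps=0.3, n_particles=100_000, seed=1)
        assert abs(frac - p) < 3.0 * max(se, 1e-6)


class TestMeanOfTwo:
    def test_identical_inputs(self, control_lungs, control_pmdi_maneuver,
                              pmdi_spec):
        r = simulate_deposition(control_lungs, control_pmdi_maneuver,
                                pmdi_spec, 1000, seed=1)
        assert mean_of_two(r, r) == (r.pd_pct, r.etd_pct)

    def test_arithmetic_and_symmetry(self):
        a = DepositionResult(20.0, 70.0, 10.0, 0.1, 0.1, np.zeros(26), 10, 0)
        b = DepositionResult(30.0, 60.0, 10.0, 0.1, 0.1, np.zeros(26), 10, 0)
        assert mean_of_two(a, b) == (25.0, 65.0)
        assert mean_of_two(a, b) == mean_of_two(b, a)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = CohortConfig(group_sizes={"Control": 2, "S-COPD": 2, "AE-COPD": 2})
    return generate_cohort(cfg, seed=4)


class TestRunCohort:
    def test_row_count_and_determinism(self, small_cohort):
        d1 = run_cohort(small_cohort, seed=8, n_particles=800)
        d2 = run_cohort(small_cohort, seed=8, n_particles=800)
        assert len(d1) == 6 * 3 * 2  # subjects x devices x repetitions
        pd.testing.assert_frame_equal(d1, d2)

    def test_missing_rows_skipped_with_run_continuing(self, small_cohort):
        broken = small_cohort.copy()
        broken.loc[broken.index[0], "ivc_d_l"] = np.nan
        d = run_cohort(broken, seed=8, n_particles=200)
        assert len(d) == len(small_cohort) - 1

    def test_row_seed_stability(self):
        s1 = row_seed(3, "C-001", "Foster_pMDI", 1)
        assert s1 == row_seed(3, "C-001", "Foster_pMDI", 1)
        assert s1 != row_seed(3, "C-001", "Foster_pMDI", 2)
        assert s1 != row_seed(4, "C-001", "Foster_pMDI", 1)
        assert 0 <= s1 < 2**31
        # repetition=None collapses both repetitions onto one stream
        assert (row_seed(3, "x", "Foster_pMDI", None)
                == row_seed(3, "x", "Foster_pMDI", None))
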