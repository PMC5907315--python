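"""Bioenergetic flux operations: printed-formula examples, limits,
singular points and gating behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurocalc import (ModelParameters, StateDomainError, ant_flux,
                       atpase_fluxes, glycolysis_fluxes, naca_flux,
                       nucleotide_pools, proton_leak, pyruvate_reduction,
                       respiration_fluxes, uniporter_flux, uniporter_mwc)
from neurocalc.params import NucleotidePools


class TestUniporter:
    def test_mwc_zero_at_zero_calcium(self, params):
        assert uniporter_mwc(0.0, params) == 0.0

    def test_mwc_hand_value(self, params):
        # CAC=6: numerator (6/6)*(1+1)^3 = 8
        expected = 8.0 / (16.0 + 50.0 / (1.0 + 6.0 / 0.38) ** 2.8)
        assert uniporter_mwc(6.0, params) == pytest.approx(expected, rel=1e-14)

    def test_fully_open_ptp_blocks_flux(self, params):
        assert uniporter_flux(1.0, 0.5, 164.0, 1.0, params) == 0.0

    def test_removable_singularity_at_91mv(self, params):
        j_at = uniporter_flux(1.0, 0.5, 91.0, 0.0, params)
        assert math.isfinite(j_at)
        # analytic limit: rho_uni * (MWC - CAM)
        limit = params.rho_uni * (uniporter_mwc(1.0, params) - 0.5)
        assert j_at == pytest.approx(limit, rel=1e-6)
        j_near = uniporter_flux(1.0, 0.5, 91.0 + 1e-7, 0.0, params)
        assert j_near == pytest.approx(j_at, rel=1e-6)

    @given(ptp_h=st.floats(0.0, 1.0))
    def test_monotone_decreasing_in_gate(self, ptp_h):
        p = ModelParameters()
        j = uniporter_flux(0.5, 0.05, 164.0, ptp_h, p)
        j_open = uniporter_flux(0.5, 0.05, 164.0, 0.0, p)
        assert j == pytest.approx(j_open * (1.0 - ptp_h), rel=1e-12)


class TestExchanger:
    def test_fully_open_ptp_blocks_flux(self, params):
        assert naca_flux(3.0, 164.0, 1.0, params) == 0.0

    def test_zero_matrix_calcium_gives_zero(self, params):
        assert naca_flux(0.0, 164.0, 0.0, params) == 0.0

    def test_saturation_limit(self, params):
        na_factor = 1.0 / (1.0 + (9.4 / 30.0) ** 2)
        j = naca_flux(1e12, 164.0, 0.0, params)
        expected = params.rho_nc * math.exp((164.0 - 91.0) / 53.4) * na_factor
        assert j == pytest.approx(expected, rel=1e-9)

    def test_half_saturation_at_91mv(self, params):
        # K_nc = 3 uM, so CAM = 3 sits exactly at half saturation
        na_factor = 1.0 / (1.0 + (9.4 / 30.0) ** 2)
        j = naca_flux(3.0, 91.0, 0.0, params)
        assert j == pytest.approx(3.0 * na_factor * 0.5, rel=1e-12)


class TestRespiration:
    def test_zero_coefficient_kills_both(self):
        p = ModelParameters(rho_res=0.0)
        j_res, j_o = respiration_fluxes(0.16, 7.84, 164.0, p)
        assert j_res == 0.0 and j_o == 0.0

    def test_depleted_nad_rejected(self, params):
        with pytest.raises(StateDomainError):
            respiration_fluxes(0.16, 0.0, 164.0, params)

    def test_finite_at_initial_state(self, params):
        j_res, j_o = respiration_fluxes(0.16, 7.84, 164.0, params)
        assert math.isfinite(j_res) and math.isfinite(j_o)
        assert j_res > 0 and j_o > 0


class TestAtpaseAnt:
    def test_zero_density_kills_both(self, params):
        p = ModelParameters(rho_F1=0.0)
        pools = nucleotide_pools(4.46, 0.028, 0.16, p)
        j_p, j_h = atpase_fluxes(pools, 164.0, p)
        assert j_p == 0.0 and j_h == 0.0

    def test_depleted_matrix_adp_rejected(self, params):
        pools = nucleotide_pools(0.0, 0.028, 0.16, params)
        with pytest.raises(StateDomainError):
            atpase_fluxes(pools, 164.0, params)

    def test_ant_zero_at_equilibrium_composition(self, params):
        # ratio product exactly cancels exp(PSI/26.7) at PSI = 0 when the
        # two composition ratios are reciprocal
        pools = NucleotidePools(ATP_m=1.0, NAD=7.84, ADP_mf=1.0, ADP_if=1.0,
                                ADP3_m=2.0, ADP3_i=1.0, MgADP_i=0.0,
                                ATP4_i=2.0, ATP4_m=4.0, ATP_i=1.0)
        assert ant_flux(pools, 0.0, params) == pytest.approx(0.0, abs=1e-15)

    def test_ant_zero_max_rate(self):
        p = ModelParameters(J_max_ANT=0.0)
        pools = nucleotide_pools(4.46, 0.028, 0.16, p)
        assert ant_flux(pools, 164.0, p) == 0.0

    def test_ant_names_empty_pool(self, params):
        pools = nucleotide_pools(4.46, 0.0, 0.16, params)
        with pytest.raises(StateDomainError, match="ADP3-"):
            ant_flux(pools, 164.0, params)


class TestLeakGlycolysisPdh:
    def test_proton_leak_values(self, params):
        assert proton_leak(-24.6, params) == pytest.approx(0.0, abs=1e-12)
        assert proton_leak(164.0, params) == pytest.approx(0.2 * 188.6)
        assert proton_leak(164.0, ModelParameters(rho_leak=0.0)) == 0.0

    def test_glycolysis_needs_atp(self, params):
        j_gly, j_p_gly, _ = glycolysis_fluxes(1.0, 0.0, params)
        assert j_gly == 0.0 and j_p_gly == 0.0

    def test_hydrolysis_saturates_in_glucose(self, params):
        _, _, j_hyd = glycolysis_fluxes(1e9, 2.0, params)
        assert j_hyd == pytest.approx(41.0 * 2.0 + 30.1, rel=1e-6)

    def test_zero_glucose_no_exception(self, params):
        j_gly, _, j_hyd = glycolysis_fluxes(0.0, 2.0, params)
        assert j_gly == 0.0
        assert j_hyd == pytest.approx(41.0 * 2.0)

    def test_glycolytic_rate_hand_value(self, params):
        num = 123.3 * (1.0 + 1.66) * (1.0 * 2.0) * 0.0249
        den = 1.0 + 8.0 + (1.0 + 5.66) * 1.3 + (1.0 + 5.32) * 0.16
        j_gly, j_p_gly, _ = glycolysis_fluxes(1.0, 2.0, params)
        assert j_gly == pytest.approx(num / den, rel=1e-12)
        assert j_p_gly == pytest.approx(2.0 * j_gly, rel=1e-15)

    def test_pdh_fraction_limits_and_value(self, params):
        f_inf, _, _ = pyruvate_reduction(1e9, 0.0, params)
        assert f_inf == pytest.approx(1.0 / 2.1, rel=1e-6)
        f_init, j_red, j_tca = pyruvate_reduction(0.05, 0.0, params)
        assert f_init == pytest.approx(1.0 / (1.0 + 1.1 * (1.0 + 15.0 / 4.0)),
                                       rel=1e-12)
        assert j_red == pytest.approx(20.0)
        assert j_tca == pytest.approx(20.0 / 3.0)


class TestFinitenessOnPhysiologicalBox:
    def test_no_nan_or_inf(self, params):
        rng = np.random.RandomState(7)
        for _ in range(100):
            cac = rng.uniform(0.01, 10.0)
            cam = rng.uniform(0.01, 10.0)
            psi = rng.uniform(100.0, 200.0)
            pools = nucleotide_pools(4.46 * rng.uniform(0.5, 1.5),
                                     0.028 * rng.uniform(0.5, 1.5),
                                     0.16 * rng.uniform(0.5, 1.5), params)
            values = [
                uniporter_flux(cac, cam, psi, rng.uniform(0, 1), params),
                naca_flux(cam, psi, rng.uniform(0, 1), params),
                *respiration_fluxes(0.16 * rng.uniform(0.5, 1.5),
                                    pools.NAD, psi, params),
                *atpase_fluxes(pools, psi, params),
                ant_flux(pools, psi, params),
                proton_leak(psi, params),
                *glycolysis_fluxes(params.glc, pools.ATP_i, params),
                *pyruvate_reduction(cam, 1.0, params),
            ]
            assert np.all(np.isfinite(values))
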