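"""Mitochondrial and cytosolic bioenergetic fluxes.

Pure scalar functions for every transport and reaction rate of the
bioenergetics subsystem: the Ca2+ uniporter (MWC allosteric form with
membrane-potential dependence), the Na+/Ca2+ exchanger, the respiratory
proton pump and O2 consumption, the F0/F1 ATPase, the adenine nucleotide
translocator, the membrane proton leak, glycolysis/hydrolysis, and the
Ca2+-activated pyruvate-dehydrogenase coupling into NADH reduction.

All rates are in the nmol/(mg*min) family of the source tables; the
empirical numerical constants inside each expression (1.35e18, 0.191,
1.71e9, ...) belong to the published kinetic forms and are kept inline,
exactly as printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import StateDomainError
from .params import ModelParameters, NucleotidePools

__all__ = [
    "FluxSet",
    "uniporter_mwc",
    "uniporter_flux",
    "naca_flux",
    "respiration_fluxes",
    "atpase_fluxes",
    "ant_flux",
    "proton_leak",
    "glycolysis_fluxes",
    "pyruvate_reduction",
]


@dataclass(frozen=True)
class FluxSet:
    """All instantaneous fluxes and gate values evaluated at one state."""

    J_uni: float
    J_nc: float
    J_res_H: float
    J_o: float
    J_p_F1: float
    J_H_F1: float
    J_H_leak: float
    J_ANT: float
    J_p_TCA: float
    J_red: float
    J_gly_total: float
    J_p_gly: float
    J_hyd: float
    J_serca: float
    J_er_out: float
    J_PTP_H: float
    J_PTP_Ca: float
    f_PDH: float
    MWC: float
    IP3: float


def uniporter_mwc(CAC: float, params: ModelParameters) -> float:
    """MWC open fraction of the Ca2+ uniporter.

    MWC = (CAC/6)*(1+CAC/6)^3 / ((1+CAC/6)^4 + 50/(1+CAC/0.38)^2.8).
    """
    q = 1.0 + CAC / 6.0
    num = (CAC / 6.0) * q ** 3
    denom = q ** 4 + 50.0 / (1.0 + CAC / 0.38) ** 2.8
    return num / denom


def uniporter_flux(CAC: float, CAM: float, PSI: float, PTP_h: float,
                   params: ModelParameters) -> float:
    """Uniporter Ca2+ influx, gated shut by the high-conductance PTP.

    J_uni = rho_uni * V_D * (MWC - CAM*exp(-V_D)) / (1 - exp(-V_D))
            * (1 - PTP_h),  V_D = (PSI - 91)/13.35.

    The 0/0 at PSI = 91 mV is removable; a first-order series in V_D is
    used for |V_D| < 1e-6 (limit rho_uni * (MWC - CAM) * (1 - PTP_h)).
    """
    p = params
    mwc = uniporter_mwc(CAC, p)
    v_d = (PSI - 91.0) / 13.35
    if abs(v_d) < 1e-6:
        # x*(MWC - CAM*e^-x)/(1-e^-x) = (MWC-CAM) + x*(CAM + (MWC-CAM)/2) + O(x^2)
        core = (mwc - CAM) + v_d * (CAM + 0.5 * (mwc - CAM))
    else:
        core = v_d * (mwc - CAM * math.exp(-v_d)) / -math.expm1(-v_d)
    return p.rho_uni * core * (1.0 - PTP_h)


def naca_flux(CAM: float, PSI: float, PTP_h: float,
              params: ModelParameters) -> float:
    """Na+/Ca2+ exchanger efflux, gated shut by the high-conductance PTP.

    J_nc = rho_nc * exp((PSI-91)/53.4) * 1/(1+(9.4/30)^2)
           * 1/(1 + K_nc/CAM) * (1 - PTP_h).

    The sodium saturation factor 1/(1+(9.4/30)^2) is a fixed constant
    (there is no Na+ state variable).  CAM = 0 returns 0: no matrix Ca2+
    to export.
    """
    p = params
    if CAM <= 0:
        return 0.0
    na_factor = 1.0 / (1.0 + (9.4 / 30.0) ** 2)
    return (p.rho_nc * math.exp((PSI - 91.0) / 53.4) * na_factor
            / (1.0 + p.K_nc / CAM) * (1.0 - PTP_h))


def respiration_fluxes(NADH_m: float, NAD: float, PSI: float,
                       params: ModelParameters) -> tuple[float, float]:
    """Respiratory proton pumping J_res_H and O2 consumption J_o.

    A_res = 1.35e18 * sqrt(NADH_m/NAD), V_res_D = exp(0.191*PSI);
    J_res_H = 360*rho_res*(r1+r2-r3)/(r4+r5),
    J_o     =  30*rho_res*(o1+o2-o3+o4)/(o5+o6).
    """
    p = params
    if NAD <= 0:
        raise StateDomainError("NAD must be > 0 (pyridine conservation violated)")
    if NADH_m < 0:
        raise StateDomainError("NADH_m must be >= 0")
    a_res = 1.35e18 * math.sqrt(NADH_m / NAD)
    v_res = math.exp(0.191 * PSI)
    r1 = 7e-7
    r2 = 2.54e-3 * a_res
    r3 = 0.639 * v_res
    r4 = 7.58e13 + 1.57e-4 * a_res
    r5 = (1.73 + a_res * 1.06e-17) * v_res
    j_res_h = 360.0 * p.rho_res * (r1 + r2 - r3) / (r4 + r5)
    o1 = a_res * 2.55e-3
    o2 = a_res * 2.00e-5
    o3 = 0.639 * v_res
    o4 = v_res * a_res * 8.63e-18
    o5 = (1.0 + a_res * 2.08e-18) * 7.54e13
    o6 = (1.73 + 1.06e-17 * a_res) * v_res
    j_o = 30.0 * p.rho_res * (o1 + o2 - o3 + o4) / (o5 + o6)
    return j_res_h, j_o


def atpase_fluxes(pools: NucleotidePools, PSI: float,
                  params: ModelParameters) -> tuple[float, float]:
    """F0/F1 ATPase phosphorylation flux J_p_F1 and proton flux J_H_F1.

    A_F1 = 1.71e9 * ATP_m / (ADP_mf * pim), V_F1_D = exp(0.112*PSI);
    J_p_F1 = -60*rho_F1*(f1-f2+f3)/(f4+f5),
    J_H_F1 = -180*rho_F1*(0.213+f1-169*V_F1_D)/(f4+f5).
    """
    p = params
    if pools.ADP_mf <= 0:
        raise StateDomainError("ADP_mf must be > 0 for the F0/F1 ATPase")
    a_f1 = 1.71e9 * pools.ATP_m / (pools.ADP_mf * p.pim)
    v_f1 = math.exp(0.112 * PSI)
    f1 = 10.5 * a_f1
    f2 = 166.0 * v_f1
    f3 = 4.85e-12 * a_f1 * v_f1
    f4 = (1e7 + 0.135 * a_f1) * 275.0
    f5 = (7.74 + 6.65e-8 * a_f1) * v_f1
    j_p_f1 = -60.0 * p.rho_F1 * (f1 - f2 + f3) / (f4 + f5)
    j_h_f1 = -180.0 * p.rho_F1 * (0.213 + f1 - 169.0 * v_f1) / (f4 + f5)
    return j_p_f1, j_h_f1


def ant_flux(pools: NucleotidePools, PSI: float,
             params: ModelParameters) -> float:
    """Adenine nucleotide translocator: matrix ATP out, cytosolic ADP in.

    ant1 = (ATP4_i/ADP3_i)*(ADP3_m/ATP4_m)*exp(-PSI/26.7);
    ant2 = 1 + (ATP4_i/ADP3_i)*exp(-PSI/53.4); ant3 = 1 + ADP3_m/ATP4_m;
    J_ANT = J_max_ANT * (1 - ant1)/(ant2*ant3).
    """
    p = params
    if pools.ADP3_i <= 0:
        raise StateDomainError("cytosolic ADP3- pool is zero in the ANT ratio")
    if pools.ATP4_m <= 0:
        raise StateDomainError("matrix ATP4- pool is zero in the ANT ratio")
    ratio_i = pools.ATP4_i / pools.ADP3_i
    ratio_m = pools.ADP3_m / pools.ATP4_m
    ant1 = ratio_i * ratio_m * math.exp(-PSI / 26.7)
    ant2 = 1.0 + ratio_i * math.exp(-PSI / 53.4)
    ant3 = 1.0 + ratio_m
    return p.J_max_ANT * (1.0 - ant1) / (ant2 * ant3)


def proton_leak(PSI: float, params: ModelParameters) -> float:
    """Inner-membrane proton leak: rho_leak * (PSI + 24.6)."""
    return params.rho_leak * (PSI + 24.6)


def glycolysis_fluxes(glc: float, ATP_i: float,
                      params: ModelParameters) -> tuple[float, float, float]:
    """Hexokinase-limited glycolysis and cytosolic ATP hydrolysis.

    J_gly_total = 123.3*(1+1.66*glc)*(glc*ATP_i)*0.0249 /
                  (1 + 4*ATP_i + (1+2.83*ATP_i)*1.3*glc
                     + (1+2.66*ATP_i)*0.16*glc^2);
    J_p_gly = 2*J_gly_total;
    J_hyd   = 41*ATP_i + J_hyd_max/(1+(8.7/glc)^2.7).

    glc = 0 sends the Hill term of J_hyd to its left limit 0 (no
    exception).
    """
    p = params
    num = 123.3 * (1.0 + 1.66 * glc) * (glc * ATP_i) * 0.0249
    denom = (1.0 + 4.0 * ATP_i
             + (1.0 + 2.83 * ATP_i) * 1.3 * glc
             + (1.0 + 2.66 * ATP_i) * 0.16 * glc * glc)
    j_gly = num / denom
    if glc <= 0:
        hill = 0.0
    else:
        hill = p.J_hyd_max / (1.0 + (8.7 / glc) ** 2.7)
    j_hyd = 41.0 * ATP_i + hill
    return j_gly, 2.0 * j_gly, j_hyd


def pyruvate_reduction(CAM: float, J_gly_total: float,
                       params: ModelParameters) -> tuple[float, float, float]:
    """Ca2+-activated PDH fraction and the NADH/TCA production it drives.

    f_PDH   = 1 / (1 + 1.1*(1 + 15/(1 + CAM/0.05)^2));
    J_red   = J_red_basal + 6.3944 * f_PDH * J_gly_total;
    J_p_TCA = J_red_basal/3 + 0.84   * f_PDH * J_gly_total.
    """
    p = params
    f_pdh = 1.0 / (1.0 + 1.1 * (1.0 + 15.0 / (1.0 + CAM / 0.05) ** 2))
    j_red = p.J_red_basal + 6.3944 * f_pdh * J_gly_total
    j_p_tca = p.J_red_basal / 3.0 + 0.84 * f_pdh * J_gly_total
    return f_pdh, j_red, j_p_tca
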