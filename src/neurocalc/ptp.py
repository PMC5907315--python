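"""Permeability-transition-pore subsystem.

A slow trigger process ``y`` integrates sustained mitochondrial Ca2+ load:
its target is heav(CAM - CAM*), so y only grows while matrix Ca2+ stays
above threshold, with a time constant that collapses from ~1e6 to ~100 as
CAM rises.  Once y crosses y* the high-conductance gate PTPh relaxes to 1
on the faster time constant tau_y/8 — an effectively irreversible switch,
since reversal would require CAM to fall and y to decay back across y*.
The low-conductance gate PTPl is pH-operated: its tanh target and sharply
peaked time constant in the matrix proton concentration H_M make it a fast
threshold element around H_M ~ p1.

The proton flux row of the source table is labelled "high conductance
state" but its printed formula uses PTPl; the formula is implemented as
printed.
"""

from __future__ import annotations

import math

from ._numerics import boltzmann_term, heav
from .params import ModelParameters

__all__ = [
    "slow_process_rate",
    "tau_slow",
    "tau_high",
    "ptp_high_rate",
    "ptp_low_rate",
    "ptp_fluxes",
    "matrix_proton_rate",
]

#: Exponent constant of the PTP proton-flux GHK-style term (1/mV).
_K_PSI = 37.434
#: Prefactor of the same term (matrix-proton concentration scale).
_H_EXT = 3.98e-8


def _sech(x: float) -> float:
    """1/cosh(x) without overflow for large |x|."""
    if abs(x) > 700.0:
        return 0.0
    return 1.0 / math.cosh(x)


def tau_slow(CAM: float) -> float:
    """Time constant of the slow trigger process:
    tau_y = 1000 * (1000/cosh(CAM/0.1) + 0.1).

    ~1e6 at resting CAM, ~100 once the matrix is loaded.
    """
    return 1000.0 * (1000.0 * _sech(CAM / 0.1) + 0.1)


def tau_high(CAM: float) -> float:
    """High-conductance gate time constant: tau_h = tau_y / 8."""
    return tau_slow(CAM) / 8.0


def slow_process_rate(CAM: float, y: float,
                      params: ModelParameters) -> tuple[float, float]:
    """dy/dt = (heav(CAM - CAM*) - y) / tau_y; returns (dy/dt, tau_y)."""
    tau_y = tau_slow(CAM)
    y_inf = heav(CAM - params.CAM_star)
    return (y_inf - y) / tau_y, tau_y


def ptp_high_rate(y: float, PTP_h: float, CAM: float,
                  params: ModelParameters) -> float:
    """dPTPh/dt = (heav(y - y*) - PTPh) / tau_h."""
    ptp_h_inf = heav(y - params.y_star)
    return (ptp_h_inf - PTP_h) / tau_high(CAM)


def ptp_low_rate(H_M: float, PTP_l: float,
                 params: ModelParameters) -> tuple[float, float]:
    """Low-conductance gate relaxation; returns (dPTPl/dt, tau_l).

    tau_l = p6 + amp_tau/cosh((H_M - p3)/p4);
    PTPl_inf = 0.5*(1 + tanh((p1 - H_M)/p2)).
    """
    p = params
    tau_l = p.p6 + p.amp_tau * _sech((H_M - p.p3) / p.p4)
    ptp_l_inf = 0.5 * (1.0 + math.tanh((p.p1 - H_M) / p.p2))
    return (ptp_l_inf - PTP_l) / tau_l, tau_l


def ptp_fluxes(PTP_l: float, PTP_h: float, PSI: float, H_M: float,
               J_uni: float, params: ModelParameters) -> tuple[float, float]:
    """Proton and Ca2+ fluxes through the pore; returns (J_PTP_H, J_PTP_Ca).

    J_PTP_H  = perm_H * PTPl * PSI * (H_M - 3.98e-8*exp(-37.434*PSI)
                                              /(1 - exp(-37.434*PSI)));
    J_PTP_Ca = perm_Ca * PTPl * J_uni * (1 - postptp*PTPh).

    The exponential ratio times PSI is evaluated through its analytic
    limit at PSI = 0, so the flux is finite for every membrane potential.
    """
    p = params
    # PSI*(H_M - c*e^{-kP}/(1-e^{-kP})) = PSI*H_M - c * PSI/expm1(k*PSI)
    j_ptp_h = p.perm_H * PTP_l * (PSI * H_M
                                  - _H_EXT * boltzmann_term(PSI, _K_PSI))
    j_ptp_ca = p.perm_Ca * PTP_l * J_uni * (1.0 - p.postptp * PTP_h)
    return j_ptp_h, j_ptp_ca


def matrix_proton_rate(J_H_leak: float, J_H_F1: float, J_res_H: float,
                       J_PTP_H: float, tau_h: float,
                       params: ModelParameters) -> float:
    """dH_M/dt = (f_HM / tau_h) * (J_H_leak + J_H_F1 - J_res_H + J_PTP_H)."""
    return (params.f_HM / tau_h) * (J_H_leak + J_H_F1 - J_res_H + J_PTP_H)
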