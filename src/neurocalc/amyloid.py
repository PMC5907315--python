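"""Beta-amyloid synthesis/elimination kinetics and the amyloid->Ca2+
entry coupling.

Amyloid ``a`` is a single generic pool (nM) covering intra- and
extracellular species of all oligomerization states.  Synthesis has a
constant basal term plus a Hill-type Ca2+-stimulated term; elimination is
first order.  Accumulated amyloid raises plasma-membrane Ca2+ permeability,
feeding the quartic entry term ``s_a * k_beta * a^m`` back into the
cytosolic Ca2+ balance — the positive feedback loop that drives pathology.
The two arms of the loop are kept as separate pure functions; only the
simulator right-hand side closes the loop.
"""

from __future__ import annotations

from .params import ModelParameters

__all__ = ["amyloid_rate", "amyloid_ca_entry", "amyloid_hill"]


def amyloid_hill(CAC: float, params: ModelParameters) -> float:
    """Ca2+-stimulation factor 1 / (1 + (K_alpha/CAC)^n), with the
    CAC -> 0 limit taken as 0 (no stimulation without calcium)."""
    if CAC <= 0:
        return 0.0
    return 1.0 / (1.0 + (params.K_alpha / CAC) ** params.n)


def amyloid_rate(CAC: float, a: float, params: ModelParameters) -> float:
    """da/dt = V1 + V_alpha / (1 + K_alpha^n / CAC^n) - K1 * a  (nM per
    unit time).

    With CAC frozen this relaxes exponentially toward
    (V1 + V_alpha*Hill(CAC)) / K1 at rate K1.
    """
    p = params
    return p.V1 + p.V_alpha * amyloid_hill(CAC, p) - p.K1 * a


def amyloid_ca_entry(a: float, params: ModelParameters) -> float:
    """Ca2+ entry rate induced by amyloid: s_a * k_beta * a^m (m = 4 by
    default; non-negative and monotone increasing in ``a``)."""
    p = params
    return p.s_a * p.k_beta * a ** p.m
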