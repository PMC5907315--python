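"""ER calcium handling: IP3 step stimulus, IP3-receptor/leak release,
SERCA uptake, and the slow inhibition gate ``h``.

The receptor uses the reduced open-probability form
``(IP3/(IP3+d_IP3))^3 * (CAC/(CAC+d_ACT))^3 * h^3`` — activation by IP3 and
cytosolic Ca2+, inhibition through the single gate ``h`` that relaxes toward
``d_INH/(CAC + d_INH)`` with time constant ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._numerics import heav
from .errors import ConfigurationError
from .params import ModelParameters

__all__ = ["StimulusSpec", "ip3_stimulus", "ip3r_leak_flux", "serca_flux",
           "h_gate_rate"]


@dataclass(frozen=True)
class StimulusSpec:
    """IP3 step stimulus: baseline + amplitude on [init, init+duration)."""

    baseline: float = 0.3   # uM
    amplitude: float = 0.3  # uM
    init: float = 10.0      # model time units
    duration: float = 100.0

    def __post_init__(self):
        if self.baseline < 0 or self.amplitude < 0:
            raise ConfigurationError("stimulus baseline and amplitude must be >= 0")
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be > 0")

    @property
    def edges(self) -> tuple[float, float]:
        """Times of the two discontinuities (step up, step down)."""
        return (self.init, self.init + self.duration)


def ip3_stimulus(t: float, stim: StimulusSpec) -> float:
    """IP3 concentration at time ``t`` (uM).

    IP3 = baseline + amplitude * (heav(t - init) - heav(t - init - duration));
    the Heaviside is right-continuous (heav(0) = 1).
    """
    up, down = stim.edges
    return stim.baseline + stim.amplitude * (heav(t - up) - heav(t - down))


def ip3r_leak_flux(CAC: float, CAER: float, IP3: float, h: float,
                   params: ModelParameters) -> float:
    """ER release through the IP3 receptor plus passive leak.

    J_er,out = (V_IP3 * (IP3/(IP3+d_IP3))^3 * (CAC/(CAC+d_ACT))^3 * h^3
               + v_leak) * (CAER - CAC); sign follows the ER->cytosol
    gradient.
    """
    p = params
    open_prob = ((IP3 / (IP3 + p.d_IP3)) ** 3
                 * (CAC / (CAC + p.d_ACT)) ** 3
                 * h ** 3)
    return (p.V_IP3 * open_prob + p.v_leak) * (CAER - CAC)


def serca_flux(CAC: float, params: ModelParameters) -> float:
    """SERCA uptake, Hill coefficient 2:
    J_serca = V_serca * CAC^2 / (k_serca^2 + CAC^2)."""
    p = params
    c2 = CAC * CAC
    return p.V_serca * c2 / (p.k_serca * p.k_serca + c2)


def h_gate_rate(CAC: float, h: float, params: ModelParameters) -> float:
    """Relaxation of the closed-channel fraction:
    dh/dt = (d_INH - (CAC + d_INH) * h) / tau.

    Fixed point h* = d_INH / (CAC + d_INH) lies in (0, 1], so h stays in
    [0, 1] along any trajectory started there.
    """
    p = params
    return (p.d_INH - (CAC + p.d_INH) * h) / p.tau
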