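"""Small numerical helpers shared by the flux modules."""

import math

__all__ = ["heav", "exp_ratio", "boltzmann_term"]


def heav(x: float) -> float:
    """Heaviside step, right-continuous convention: 1 for x >= 0, else 0."""
    return 1.0 if x >= 0 else 0.0


def exp_ratio(x: float) -> float:
    """x / (1 - exp(-x)) with the removable singularity at x = 0 filled.

    Series x/(1-e^-x) = 1 + x/2 + x^2/12 + O(x^4) is used for |x| < 1e-6.
    """
    if abs(x) < 1e-6:
        return 1.0 + 0.5 * x + x * x / 12.0
    return x / -math.expm1(-x)


def boltzmann_term(psi: float, k: float) -> float:
    """psi * exp(-k*psi) / (1 - exp(-k*psi)) = psi / expm1(k*psi).

    Finite everywhere: -> 1/k as psi -> 0, -> 0 for large positive k*psi,
    and ~ -psi for large negative k*psi.
    """
    kp = k * psi
    if abs(kp) < 1e-8:
        return (1.0 - 0.5 * kp) / k
    if kp > 700.0:
        return 0.0
    return psi / math.expm1(kp)
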