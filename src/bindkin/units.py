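"""Physical constants and unit conversions used across the package.

Conventions: energies in kcal/mol, assay time in minutes, toy-dynamics time in
ps (reported in ns), physical unbinding times in seconds, distances in Å,
concentrations in nM.
"""

import math

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL = 0.0019872041

LN2 = math.log(2.0)

NS_PER_PS = 1e-3
S_PER_NS = 1e-9
S_PER_MIN = 60.0


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at `temperature` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature


def half_life_from_rate(k: float) -> float:
    """t_1/2 = ln2 / k for a first-order rate constant (same time unit)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return LN2 / k


def half_life_from_tau(tau: float) -> float:
    """t_1/2 = tau·ln2 for an exponential characteristic time."""
    return tau * LN2
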