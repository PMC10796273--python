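"""Physical constants used by the kinetics formulas.

The decade factor is fixed at 2.3 (not 2.303) so that hand evaluations of the
peak-shift slope relation reproduce the printed working formula exactly.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Read-only constants for electrochemical rate expressions.

    Attributes
    ----------
    F : float
        Faraday constant, C mol^-1.
    R : float
        Gas constant, J mol^-1 K^-1.
    decade_factor : float
        ln(10) as conventionally rounded in the peak-shift slope formula.
    """

    F: float = 96485.0
    R: float = 8.314
    decade_factor: float = 2.3


CONSTANTS = PhysicalConstants()

#: Default laboratory temperature (K) when none is given.
ROOM_TEMPERATURE_K = 298.15


def f_over_rt(temperature_K: float = ROOM_TEMPERATURE_K) -> float:
    """Return F/(R*T) in V^-1 at the given temperature."""
    return CONSTANTS.F / (CONSTANTS.R * temperature_K)
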