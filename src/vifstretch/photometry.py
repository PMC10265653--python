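"""Degree of labeling from UV-vis absorbances.

For a maleimide-coupled dye on a protein, the dye-to-protein molar ratio
(degree of labeling, DOL) follows from the absorbance at the dye maximum
and at 280 nm, after correcting the 280 nm reading for the dye's own
absorption there:

    DOL = (A_dye / eps_dye) / ((A_280 - f * A_dye) / eps_280)

Defaults match ATTO647N on vimentin: eps_280 = 24,240 L/(mol cm),
eps_dye = 1.5e5 L/(mol cm), correction factor f = 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class AbsorbanceReading:
    A_max_dye: float
    A_280: float
    eps_280: float = 24_240.0
    eps_dye: float = 1.5e5
    f: float = 0.03

    def __post_init__(self):
        if self.A_max_dye < 0 or self.A_280 < 0:
            raise ValueError("absorbances must be non-negative")
        if self.eps_280 <= 0 or self.eps_dye <= 0:
            raise ValueError("extinction coefficients must be positive")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("correction factor must lie in [0, 1)")


def degree_of_labeling(reading: AbsorbanceReading) -> float:
    """Dye molarity over protein molarity."""
    protein = (reading.A_280 - reading.f * reading.A_max_dye) / reading.eps_280
    if protein <= 0:
        raise ValueError("no protein signal: corrected A280 is non-positive")
    dye = reading.A_max_dye / reading.eps_dye
    return dye / protein
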