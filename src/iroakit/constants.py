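"""Physical constants for the mass scale.

Monoisotopic atomic masses (CODATA/AME-derived values as commonly tabulated
in mass spectrometry software) and the carbon isotope mass difference that
sets the spacing of IROA peak pairs.
"""

from __future__ import annotations

#: Mass difference between 13C and 12C, in Da. One backbone carbon swapped
#: from 12C to 13C shifts an ion by exactly this amount.
DELTA_13C: float = 1.0033548

#: Monoisotopic atomic masses in Da (most abundant isotope).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Si": 27.9769265325,
    "S": 31.97207100,
}

#: Elements supported by formula enumeration, heaviest first (enumeration
#: order matters for pruning efficiency, hydrogen is solved last).
SUPPORTED_ELEMENTS: tuple[str, ...] = ("S", "Si", "O", "N", "C", "H")

#: Mass of a proton in Da, for [MH]+ adduct arithmetic.
PROTON_MASS: float = 1.00727646688


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Sum of monoisotopic atomic masses for an atom-count mapping.

    Unknown element symbols raise ``KeyError``; an empty mapping gives 0.0.
    """
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())
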