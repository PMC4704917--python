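"""Energy unit conversion.

The thermochemical factor 4.184 kJ/kcal is used everywhere in the package;
it reproduces the conventional integer pairs 500 kcal = 2092 kJ and
200 kcal = 837 kJ (after rounding to whole kJ).
"""

KJ_PER_KCAL: float = 4.184


def kcal_to_kj(kcal: float) -> float:
    """Convert kilocalories to kilojoules (exact, unrounded)."""
    return kcal * KJ_PER_KCAL


def kj_to_kcal(kj: float) -> float:
    """Convert kilojoules to kilocalories (exact, unrounded)."""
    return kj / KJ_PER_KCAL
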