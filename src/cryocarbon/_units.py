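"""Unit conversion constants.

All model state is carried in femtograms of carbon (fg C), millilitres
(cm^3 and mL are treated as the same volume unit), and days.  Field
measurements arrive in micrograms and grams; the exact integer scalings
below are the only place mass-unit conversions happen.
"""

FG_PER_UG: int = 10**9
FG_PER_G: int = 10**15

#: Molar mass of carbon, g mol^-1.
CARBON_MOLAR_MASS: float = 12.011

#: Default calendar length of a year in days.  365.0 reproduces the same
#: printed 3-significant-figure results; exposed so callers can choose.
DAYS_PER_YEAR: float = 365.25

SECONDS_PER_DAY: float = 86_400.0


def ug_to_fg(x: float) -> float:
    """Convert micrograms to femtograms (exact integer scaling)."""
    return x * FG_PER_UG


def g_to_fg(x: float) -> float:
    """Convert grams to femtograms (exact integer scaling)."""
    return x * FG_PER_G
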