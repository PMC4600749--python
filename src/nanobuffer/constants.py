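"""Physical constants and library-wide model defaults.

Units are stated per name.  Defaults that describe the ultra-pH-sensitive
(UPS) copolymer platform are documented, overridable starting points, not
fitted quantities; see docs/methods.md for provenance of each value.
"""

import math

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Water autoionization product at 25 degC, (mol/L)^2.  pH = -log10[H+].
KW = 1e-14

#: 10-90% protonation transition width of a UPS micelle, pH units.
TRANSITION_WIDTH_PH = 0.25


def hill_n_for_width(width_ph: float) -> float:
    """Hill coefficient whose 10-90% protonation span equals ``width_ph``.

    The Hill closure f = 1/(1 + 10^(n (pH - pKa))) crosses f = 0.9 and
    f = 0.1 at pKa -/+ log10(9)/n, so width = 2 log10(9)/n.
    """
    if width_ph <= 0:
        raise ValueError("transition width must be positive")
    return 2.0 * math.log10(9.0) / width_ph


def width_for_hill_n(hill_n: float) -> float:
    """10-90% protonation span (pH units) of a Hill group."""
    if hill_n <= 0:
        raise ValueError("hill_n must be positive")
    return 2.0 * math.log10(9.0) / hill_n


#: Default cooperativity: realizes the 0.25 pH-unit micelle transition.
DEFAULT_HILL_N = hill_n_for_width(TRANSITION_WIDTH_PH)  # ~7.634

#: Tertiary-amine density of the UPS copolymer, mol protonatable sites per
#: gram (PEO114 macroinitiator + ~80 amine monomers per chain).
UPS_SITE_DENSITY_MOL_PER_G = 3.2e-3

#: Amino groups per assembled micelle.
AMINES_PER_MICELLE = 64_000

#: Average endosome/lysosome count per cell used in rate bookkeeping.
ORGANELLES_PER_CELL = 200

#: Chloroquine comparator: diprotic base.
CQ_PKAS = (8.3, 10.4)
#: Chloroquine free-base molar mass, g/mol (C18H26ClN3).
CQ_MOLAR_MASS_G_PER_MOL = 319.87
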