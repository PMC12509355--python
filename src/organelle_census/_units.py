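"""Physical constants and unit conversions.

Internal conventions: volumes in µm³, lengths in nm, masses in g/mol
(molecular weights) or pg (bulk RNA mass). All conversions live here.
"""

#: Avogadro constant, molecules per mole.
AVOGADRO = 6.02214076e23

#: nm³ per µm³.
NM3_PER_UM3 = 1.0e9

#: litres per µm³.
LITRES_PER_UM3 = 1.0e-15

#: grams per picogram.
G_PER_PG = 1.0e-12

#: average molecular weight of one bp of double-stranded DNA, g/mol.
DNA_BP_MW = 650.0

#: histone octamer molecular weight, g/mol.
HISTONE_OCTAMER_MW = 108_000.0


def copies_to_micromolar(copies: float, volume_um3: float) -> float:
    """Convert a copy number in a volume (µm³) to a concentration in µM."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return copies / (AVOGADRO * volume_um3 * LITRES_PER_UM3) * 1.0e6


def copies_to_mg_per_ml(copies: float, mw_da: float, volume_um3: float) -> float:
    """Convert copies of a species with molecular weight ``mw_da`` (g/mol)
    in a volume (µm³) to a mass density in mg/mL."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    grams = copies * mw_da / AVOGADRO
    millilitres = volume_um3 * LITRES_PER_UM3 * 1.0e3
    return grams * 1.0e3 / millilitres
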