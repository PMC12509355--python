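"""Absolute abundance census: iBAQ calibration, organelle partitioning,
RNA and nucleosome pools, mass densities.

The census rests on a two-pool decomposition of each nuclear species:
copies inside the ``n_org`` organelles of a class (at average
concentration ``c_org``) and copies in the surrounding nucleoplasm
(``c_np``), with the ratio ``α = c_org/c_np`` measured from
background-subtracted image intensities. Solving the conservation
relation ``N_tot = n_org·V_org·c_org + (V_nuc − n_org·V_org)·c_np``
for ``c_org`` gives the partition used throughout:

    N_org = α·N_tot·V_org / ((α−1)·n_org·V_org + V_nuc)

The α → ∞ limit (exclusive localization) is N_tot/n_org.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._units import (
    AVOGADRO,
    DNA_BP_MW,
    G_PER_PG,
    HISTONE_OCTAMER_MW,
    copies_to_mg_per_ml,
    copies_to_micromolar,
)
from .model_io import (
    CalibrationModel,
    CalibrationRef,
    CensusEntry,
    NucleusModel,
    OrganelleModel,
    ProteinSpecies,
)

__all__ = [
    "theoretical_h4_total",
    "fit_calibration",
    "total_copies",
    "enrichment_from_intensities",
    "organelle_copies",
    "nucleoplasm_concentration",
    "rna_census",
    "nucleosome_census",
    "dna_content",
    "expected_satellite_dna",
    "mass_density",
    "nucleosome_mw",
    "RnaPool",
]


def theoretical_h4_total(nuc: NucleusModel) -> float:
    """Theoretical whole-cell histone H4 copy number.

    Two H4 per nucleosome, one nucleosome per repeat length of genomic
    DNA, ``ploidy`` genome copies:
    ``ploidy · 2 · genome_size / NRL`` (≈ 5.4×10⁷ for the diploid
    mouse defaults).
    """
    return nuc.ploidy * 2.0 * nuc.genome_size_haploid / nuc.nucleosome_repeat_length


def fit_calibration(refs: Sequence[CalibrationRef]) -> CalibrationModel:
    """Least-squares slope of measured copies on iBAQ through the origin.

    The calibration has a single scale parameter ``a`` (copies per iBAQ
    unit): a = Σxy/Σx². The reported standard error is the textbook
    through-origin OLS value sqrt(Σr²/(n−1)/Σx²) (NaN for n = 1).
    """
    if not refs:
        raise ValueError("at least one calibration reference is required")
    x = np.array([r.ibaq for r in refs], dtype=float)
    y = np.array([r.measured_copies for r in refs], dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("calibration references must have positive values")
    sxx = float(np.dot(x, x))
    a = float(np.dot(x, y)) / sxx
    if len(refs) > 1:
        resid = y - a * x
        stderr = math.sqrt(float(np.dot(resid, resid)) / (len(refs) - 1) / sxx)
    else:
        stderr = float("nan")
    return CalibrationModel(scale_a=a, refs=tuple(refs), stderr=stderr)


def total_copies(
    species: ProteinSpecies, calib: CalibrationModel | None, nuc: NucleusModel
) -> float:
    """Whole-cell copy number of a species.

    A direct ``total_copies`` overrides the iBAQ path. Otherwise
    ``a·iBAQ``; a zero iBAQ means the protein was not detected by mass
    spectrometry and receives the detection-limit copy number (407 by
    default).
    """
    if species.total_copies is not None:
        return float(species.total_copies)
    if species.ibaq is None or species.ibaq == 0:
        return float(nuc.detection_limit_copies)
    if calib is None:
        raise ValueError(f"species {species.name!r} has iBAQ but no calibration given")
    return calib.scale_a * float(species.ibaq)


def enrichment_from_intensities(i_org: float, i_np: float, i_bg: float) -> float:
    """Enrichment α = (I_org − I_BG)/(I_np − I_BG) from average image
    intensities in the organelle, the nucleoplasm, and the background."""
    if i_np <= i_bg:
        raise ValueError("nucleoplasm intensity must exceed background (α undefined)")
    return (i_org - i_bg) / (i_np - i_bg)


def organelle_copies(
    n_tot: float, alpha: float, org: OrganelleModel, nuc: NucleusModel
) -> tuple[float, float]:
    """Copies per organelle and concentration (µM) from the two-pool partition.

    Returns ``(N_org, c_org)``. α = inf returns the analytic exclusive-
    localization limit N_tot/n_org.
    """
    if not alpha >= 0:
        raise ValueError("alpha must be >= 0")
    if math.isinf(alpha):
        n_org = n_tot / org.count_per_nucleus
    else:
        denom = (alpha - 1.0) * org.count_per_nucleus * org.volume + nuc.nucleus_volume
        if denom <= 0:
            raise ValueError("partition denominator must be positive")
        n_org = alpha * n_tot * org.volume / denom
    return n_org, copies_to_micromolar(n_org, org.volume)


def nucleoplasm_concentration(
    n_tot: float, alpha: float, org: OrganelleModel, nuc: NucleusModel
) -> float:
    """Nucleoplasm copies per µm³ consistent with the organelle partition."""
    v_np = nuc.nucleus_volume - org.count_per_nucleus * org.volume
    if math.isinf(alpha):
        return 0.0
    n_org, _ = organelle_copies(n_tot, alpha, org, nuc)
    return (n_tot - org.count_per_nucleus * n_org) / v_np


@dataclass(frozen=True)
class RnaPool:
    """Nuclear ribonucleotide budget partitioned over organelles.

    Conservation: ``total = nucleoplasm pool + Σ_i n_org,i · per-organelle
    pool_i``.
    """

    total_ribonucleotides: float
    nucleoplasm_concentration: float  # ribonucleotides per µm³
    nucleoplasm_ribonucleotides: float
    per_organelle_ribonucleotides: Mapping[str, float]  # per single organelle
    per_organelle_molecules: Mapping[str, float]  # fractional; round for reports


def rna_census(nuc: NucleusModel, organelles: Sequence[OrganelleModel]) -> RnaPool:
    """Partition the nuclear ribonucleotide pool over organelles.

    The nuclear RNA mass ``M_tot·f_nuc`` is converted to a ribonucleotide
    count via the monophosphate molecular weight and Avogadro's number,
    then distributed by RNA enrichments:
    ``c_rn,np = N_rn,tot / (V_np + Σ_i α_i·n_i·V_i)`` and
    ``N_rn,org,i = c_rn,np·α_i·V_i`` per organelle. Molecule counts are
    ribonucleotides divided by the organelle's typical RNA length
    (fractional values allowed).
    """
    v_occupied = sum(o.count_per_nucleus * o.volume for o in organelles)
    v_np = nuc.nucleus_volume - v_occupied
    if v_np <= 0:
        raise ValueError("nucleoplasm volume must be positive")
    n_rn_tot = nuc.total_rna_mass * G_PER_PG * nuc.nuclear_rna_fraction / nuc.ribonucleotide_mw * AVOGADRO
    weighted = sum(o.rna_enrichment * o.count_per_nucleus * o.volume for o in organelles)
    c_rn_np = n_rn_tot / (v_np + weighted)
    per_org = {o.name: c_rn_np * o.rna_enrichment * o.volume for o in organelles}
    molecules = {o.name: per_org[o.name] / o.rna_length for o in organelles}
    return RnaPool(
        total_ribonucleotides=n_rn_tot,
        nucleoplasm_concentration=c_rn_np,
        nucleoplasm_ribonucleotides=c_rn_np * v_np,
        per_organelle_ribonucleotides=per_org,
        per_organelle_molecules=molecules,
    )


def nucleosome_census(
    nuc: NucleusModel, org: OrganelleModel, h4_total: float
) -> float:
    """Nucleosomes per organelle from the H4 budget and DAPI enrichment.

    The whole-cell nucleosome number is ``h4_total/2`` (two H4 per
    nucleosome). For satellite-rich organelles (``dapi_bias_correction``)
    the supplied DAPI enrichment is divided by the satellite bias (1.5)
    before the two-pool partition, correcting for DAPI's preference for
    AT-rich repeats.
    """
    if h4_total <= 0:
        raise ValueError("h4_total must be positive")
    nucleosome_total = h4_total / 2.0
    alpha = org.nucleosome_enrichment
    if org.dapi_bias_correction:
        alpha = alpha / nuc.dapi_satellite_bias
    n_org, _ = organelle_copies(nucleosome_total, alpha, org, nuc)
    return n_org


def dna_content(nucleosomes: float, nuc: NucleusModel) -> float:
    """DNA length (bp) wrapped in and linking ``nucleosomes`` nucleosomes."""
    if nucleosomes < 0:
        raise ValueError("nucleosomes must be >= 0")
    return nucleosomes * nuc.nucleosome_repeat_length


def expected_satellite_dna(
    nuc: NucleusModel,
    genome_satellite_fraction: float = 0.03,
    focus_satellite_fraction: float = 0.66,
) -> float:
    """Expected DNA (bp) in all heterochromatin foci of a nucleus.

    Major-satellite repeats make up ``genome_satellite_fraction`` of the
    genome and ``focus_satellite_fraction`` of focus DNA, so the foci
    hold ``ploidy·genome·(3%/66%) ≈ 230 Mb`` for the diploid defaults.
    """
    return (
        nuc.ploidy
        * nuc.genome_size_haploid
        * genome_satellite_fraction
        / focus_satellite_fraction
    )


def nucleosome_mw(nuc: NucleusModel) -> float:
    """Nucleosome molecular weight (g/mol): histone octamer plus one
    repeat length of double-stranded DNA (~229 kDa at 186 bp)."""
    return HISTONE_OCTAMER_MW + nuc.nucleosome_repeat_length * DNA_BP_MW


def mass_density(
    entries: Sequence[CensusEntry],
    org: OrganelleModel,
    mw_by_species: Mapping[str, float],
) -> dict[str, float]:
    """Mass density (mg/mL) per species class in one organelle.

    ``mw_by_species`` maps species name to molecular weight in g/mol;
    every entry must be covered.
    """
    density: dict[str, float] = {"protein": 0.0, "rna": 0.0, "nucleosome": 0.0}
    for e in entries:
        if e.organelle != org.name:
            continue
        if e.species not in mw_by_species:
            raise ValueError(f"no molecular weight provided for species {e.species!r}")
        density[e.species_class] += copies_to_mg_per_ml(
            e.copies_in_organelle, mw_by_species[e.species], org.volume
        )
    return density
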