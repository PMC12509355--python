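"""End-to-end census workflow.

Given a cell configuration (nucleus, organelles, calibration anchors)
and a candidate-scaffold species table, this module produces, per
organelle: the molecular census (protein, RNA and nucleosome copies,
concentrations and mass densities), packing states for the three
multicomponent scenarios under each conformation, and a Debye-length
scorecard. Scorecards use the relaxed conformation, the intermediate
of the three size models.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from . import abundance, conformers, packing, scoring
from ._units import copies_to_mg_per_ml, copies_to_micromolar
from .conformers import MoleculeGeometry
from .model_io import (
    CalibrationModel,
    CellConfig,
    CensusEntry,
    NucleusModel,
    OrganelleModel,
    PackingState,
    ProteinSpecies,
    ScoreCard,
)

__all__ = ["CensusResult", "build_geometries", "census_entries", "run_census"]

SCENARIOS = tuple(packing.SCENARIO_CLASSES)
CONFORMATIONS = conformers.PROTEIN_CONFORMATIONS


def _rna_species_name(org: OrganelleModel) -> str:
    return f"RNA_{org.name}"


def build_geometries(
    species: Sequence[ProteinSpecies],
    organelles: Sequence[OrganelleModel],
) -> dict[tuple[str, str], MoleculeGeometry]:
    """Diameters for every species × conformation.

    Proteins get predicted/relaxed/expanded diameters from their domain
    decompositions; each organelle's RNA pool gets folded/relaxed/
    expanded worm-like-chain diameters for its typical RNA length;
    nucleosomes keep the crystal-structure disk diameter in every
    conformation.
    """
    geoms: dict[tuple[str, str], MoleculeGeometry] = {}
    for sp in species:
        diameters = conformers.protein_diameters(sp)
        for conf, d in diameters.items():
            geoms[(sp.name, conf)] = MoleculeGeometry(sp.name, conf, d)
    for org in organelles:
        name = _rna_species_name(org)
        for conf in conformers.RNA_CONFORMATIONS:
            geoms[(name, conf)] = MoleculeGeometry(
                name, conf, conformers.rna_diameter(org.rna_length, conf)
            )
    for conf in CONFORMATIONS:
        geoms[("nucleosome", conf)] = MoleculeGeometry(
            "nucleosome", conf, conformers.NUCLEOSOME_DIAMETER
        )
    return geoms


def census_entries(
    nuc: NucleusModel,
    organelles: Sequence[OrganelleModel],
    species: Sequence[ProteinSpecies],
    calibration: CalibrationModel | None,
) -> list[CensusEntry]:
    """Molecular census of every organelle.

    Protein copies come from the iBAQ calibration (or direct counts) and
    the two-pool enrichment partition; RNA from the nuclear
    ribonucleotide budget; nucleosomes from the theoretical H4 total.
    Each species' enrichment α is applied organelle by organelle.
    """
    entries: list[CensusEntry] = []
    rna_pool = abundance.rna_census(nuc, organelles)
    h4 = abundance.theoretical_h4_total(nuc)
    for org in organelles:
        for sp in species:
            n_tot = abundance.total_copies(sp, calibration, nuc)
            n_org, conc = abundance.organelle_copies(n_tot, sp.enrichment, org, nuc)
            entries.append(
                CensusEntry(
                    species=sp.name,
                    species_class="protein",
                    organelle=org.name,
                    copies_in_organelle=n_org,
                    concentration=conc,
                    mass_density=copies_to_mg_per_ml(n_org, sp.mw, org.volume),
                )
            )
        rn = rna_pool.per_organelle_ribonucleotides[org.name]
        molecules = rna_pool.per_organelle_molecules[org.name]
        rna_mw = org.rna_length * nuc.ribonucleotide_mw
        entries.append(
            CensusEntry(
                species=_rna_species_name(org),
                species_class="rna",
                organelle=org.name,
                copies_in_organelle=molecules,
                concentration=copies_to_micromolar(molecules, org.volume),
                mass_density=copies_to_mg_per_ml(molecules, rna_mw, org.volume),
            )
        )
        nucleosomes = abundance.nucleosome_census(nuc, org, h4)
        entries.append(
            CensusEntry(
                species="nucleosome",
                species_class="nucleosome",
                organelle=org.name,
                copies_in_organelle=nucleosomes,
                concentration=copies_to_micromolar(nucleosomes, org.volume),
                mass_density=copies_to_mg_per_ml(
                    nucleosomes, abundance.nucleosome_mw(nuc), org.volume
                ),
            )
        )
    return entries


@dataclass(frozen=True)
class CensusResult:
    """Everything the workflow computes for one cell configuration."""

    config: CellConfig
    calibration: CalibrationModel | None
    entries: tuple[CensusEntry, ...]
    geometries: Mapping[tuple[str, str], MoleculeGeometry]
    packing_states: Mapping[tuple[str, str, str], PackingState]  # (org, scenario, conf)
    scorecards: tuple[ScoreCard, ...]


def run_census(
    config: CellConfig,
    conformations: Sequence[str] = CONFORMATIONS,
    scoring_conformation: str = "relaxed",
) -> CensusResult:
    """Run the full workflow: census → packing → scoring."""
    calibration = (
        abundance.fit_calibration(config.calibration_refs)
        if config.calibration_refs
        else None
    )
    entries = census_entries(config.nucleus, config.organelles, config.species, calibration)
    geometries = build_geometries(config.species, config.organelles)
    states: dict[tuple[str, str, str], PackingState] = {}
    for org in config.organelles:
        for scenario in SCENARIOS:
            for conf in conformations:
                states[(org.name, scenario, conf)] = packing.scenario_distances(
                    entries, geometries, scenario, conf, org.name, org.volume
                )
    cards = []
    if config.species:
        for org in config.organelles:
            distances = {
                scenario: states[(org.name, scenario, scoring_conformation)].surface_distance
                for scenario in SCENARIOS
            }
            cards.append(
                scoring.score_card(
                    org.name,
                    distances,
                    entries,
                    lambda_d=config.nucleus.debye_length_max,
                )
            )
    return CensusResult(
        config=config,
        calibration=calibration,
        entries=tuple(entries),
        geometries=geometries,
        packing_states=states,
        scorecards=tuple(cards),
    )
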