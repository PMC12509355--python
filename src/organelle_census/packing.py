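"""Crowding metrics and mean nearest-neighbor distances for hard spheres.

For ``N`` molecules of radius ``r`` randomly placed in a volume, the mean
center-to-center nearest-neighbor distance follows the hard-sphere
statistic

    Δ_center = 2r + e^{8φ} · r / (3 φ^{1/3}) · Γ(1/3, 8φ)

with volume fraction φ = (4π/3)r³/V_available and Γ the *unnormalized*
upper incomplete gamma function. In the dilute limit this reduces to the
Poisson point-process mean Γ(4/3)·(4πn/3)^{-1/3}. The surface-to-surface
distance subtracts the diameter; beyond random close packing (φ ≥ 0.65)
molecules touch and the surface distance is defined as zero.

Mixtures are mapped onto an effective one-component system via the
count-weighted third-moment radius r_avg = (Σ N_i (d_i/2)³ / Σ N_i)^{1/3}.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.special import gamma as _gamma_fn
from scipy.special import gammaincc

from ._units import NM3_PER_UM3
from .conformers import MoleculeGeometry, molecule_volume
from .model_io import CensusEntry, PackingState

logger = logging.getLogger("organelle_census")

__all__ = [
    "RANDOM_CLOSE_PACKING",
    "MixtureComponent",
    "available_volume",
    "volume_fraction",
    "nn_center_distance",
    "nn_surface_distance",
    "effective_radius",
    "overlap_ratio",
    "scenario_distances",
    "SCENARIO_CLASSES",
]

#: Volume fraction of random close packing of rigid spheres.
RANDOM_CLOSE_PACKING = 0.65

#: Molecule classes entering each multicomponent scenario.
SCENARIO_CLASSES = {
    "proteins_only": ("protein",),
    "proteins_rna": ("protein", "rna"),
    "proteins_rna_nucleosomes": ("protein", "rna", "nucleosome"),
}


@dataclass(frozen=True)
class MixtureComponent:
    """Copy number and diameter of one species in a mixture."""

    species: str
    copies: float
    diameter: float  # nm

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


def available_volume(v_org_um3: float, n_molecules: float) -> float:
    """Volume available per molecule, nm³ (V_org/N)."""
    if n_molecules <= 0:
        raise ValueError("n_molecules must be >= 1")
    return v_org_um3 * NM3_PER_UM3 / n_molecules


def volume_fraction(r_nm: float, v_available_nm3: float) -> float:
    """φ = (4π/3) r³ / V_available."""
    if r_nm <= 0 or v_available_nm3 <= 0:
        raise ValueError("radius and available volume must be positive")
    return (4.0 * math.pi / 3.0) * r_nm**3 / v_available_nm3


def _upper_incomplete_gamma_13(x: float) -> float:
    # unnormalized upper incomplete gamma Γ(1/3, x)
    return float(gammaincc(1.0 / 3.0, x) * _gamma_fn(1.0 / 3.0))


def nn_center_distance(r_nm: float, phi: float) -> float:
    """Mean center-to-center nearest-neighbor distance, nm.

    Evaluated analytically, then clamped to the contact value 2r at and
    beyond random close packing.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    analytic = 2.0 * r_nm + (
        math.exp(8.0 * phi) * r_nm / (3.0 * phi ** (1.0 / 3.0))
    ) * _upper_incomplete_gamma_13(8.0 * phi)
    if phi >= RANDOM_CLOSE_PACKING:
        return 2.0 * r_nm
    return analytic


def nn_surface_distance(r_nm: float, phi: float) -> float:
    """Mean surface-to-surface nearest-neighbor distance, nm (≥ 0)."""
    return nn_center_distance(r_nm, phi) - 2.0 * r_nm


def effective_radius(components: Sequence[MixtureComponent]) -> float:
    """Count-weighted third-moment average radius of a mixture, nm.

    r_avg = (Σ N_i (d_i/2)³ / Σ N_i)^{1/3}; reduces to d/2 for one
    component and is invariant to duplicating the component list.
    """
    total = sum(c.copies for c in components)
    if total <= 0:
        raise ValueError("mixture must contain at least one molecule")
    if len(components) == 1:  # exact one-component reduction
        return components[0].diameter / 2.0
    third_moment = sum(c.copies * (c.diameter / 2.0) ** 3 for c in components)
    return math.cbrt(third_moment / total)


def overlap_ratio(components: Sequence[MixtureComponent], v_org_um3: float) -> float:
    """Density relative to the overlap concentration: Σ N_i·V_i / V_org.

    At 1.0 the molecules' pervaded volumes exactly tile the organelle.
    """
    if v_org_um3 <= 0:
        raise ValueError("organelle volume must be positive")
    pervaded = sum(c.copies * molecule_volume(c.diameter) for c in components)
    return pervaded / (v_org_um3 * NM3_PER_UM3)


def _rna_conformation(conformation: str) -> str:
    return "folded" if conformation == "predicted" else conformation


def components_for_scenario(
    entries: Sequence[CensusEntry],
    geometries: Mapping[tuple[str, str], MoleculeGeometry],
    scenario: str,
    conformation: str,
    organelle: str,
) -> list[MixtureComponent]:
    """Assemble the mixture for one scenario × conformation in one organelle.

    ``geometries`` maps (species, conformation) to a
    :class:`MoleculeGeometry`; RNA entries use the folded geometry for
    the predicted conformation.
    """
    if scenario not in SCENARIO_CLASSES:
        raise ValueError(f"unknown scenario {scenario!r}")
    classes = SCENARIO_CLASSES[scenario]
    components = []
    for e in entries:
        if e.organelle != organelle or e.species_class not in classes:
            continue
        conf = _rna_conformation(conformation) if e.species_class == "rna" else conformation
        key = (e.species, conf)
        if key not in geometries:
            raise KeyError(f"no geometry for species {e.species!r} conformation {conf!r}")
        components.append(
            MixtureComponent(
                species=e.species,
                copies=e.copies_in_organelle,
                diameter=geometries[key].diameter,
            )
        )
    return components


def scenario_distances(
    entries: Sequence[CensusEntry],
    geometries: Mapping[tuple[str, str], MoleculeGeometry],
    scenario: str,
    conformation: str,
    organelle: str,
    v_org_um3: float,
) -> PackingState:
    """Full packing state for one scenario × conformation.

    Computes r_avg, φ = (4π/3) r_avg³ · ΣN_i / V_org, the nearest-
    neighbor distances, and the overlap ratio. If the scenario's classes
    hold no molecules a zero-φ state is returned with a warning.
    """
    components = components_for_scenario(entries, geometries, scenario, conformation, organelle)
    total = sum(c.copies for c in components)
    if total <= 0:
        logger.warning(
            "scenario %r in organelle %r contains no molecules; returning empty state",
            scenario,
            organelle,
        )
        return PackingState(
            scenario=scenario,
            conformation=conformation,
            effective_radius=0.0,
            volume_fraction=0.0,
            center_distance=math.inf,
            surface_distance=math.inf,
            overlap_ratio=0.0,
        )
    r_avg = effective_radius(components)
    v_avail = available_volume(v_org_um3, total)
    phi = volume_fraction(r_avg, v_avail)
    center = nn_center_distance(r_avg, phi)
    surface = nn_surface_distance(r_avg, phi)
    return PackingState(
        scenario=scenario,
        conformation=conformation,
        effective_radius=r_avg,
        volume_fraction=phi,
        center_distance=center,
        surface_distance=surface,
        overlap_ratio=overlap_ratio(components, v_org_um3),
    )
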