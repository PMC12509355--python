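"""Molecular sizes under explicit conformation models.

Proteins are assigned three diameters: the structure-predicted one
(twice the predicted radius of gyration), a "relaxed" one in which the
ordered and disordered domains form a random walk (d = 2·sqrt(Σ Rg²),
floored at the predicted diameter), and an "expanded" one midway between
the relaxed arrangement and all domains laid out in a straight line
(d = Σ Rg + sqrt(Σ Rg²), capped at the fully denatured chain and floored
at the relaxed diameter so the three sizes are ordered).

RNAs follow a folded scaling law d = 2·0.55·N^0.33 nm and a worm-like
chain for the expanded conformation (persistence length 0.15·N^0.33 nm,
contour length 0.696 nm·N); relaxed is the arithmetic mean of the two.
Nucleosomes are 11 nm disks-as-spheres in every conformation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .model_io import DomainSegment, ProteinSpecies, ScalingLaw

__all__ = [
    "DISORDERED_RG_LAW",
    "DENATURED_RG_LAW",
    "NUCLEOSOME_DIAMETER",
    "PROTEIN_CONFORMATIONS",
    "RNA_CONFORMATIONS",
    "MoleculeGeometry",
    "segment_domains",
    "rg_disordered",
    "resolve_domain_rgs",
    "diameter_relaxed",
    "diameter_expanded",
    "protein_diameters",
    "rna_diameter",
    "molecule_volume",
]

#: Radius-of-gyration scaling for intrinsically disordered chains
#: (substitutable; coefficients are configuration, not measured here).
DISORDERED_RG_LAW = ScalingLaw(prefactor=0.254, exponent=0.522)

#: Radius-of-gyration scaling for fully denatured chains (substitutable).
DENATURED_RG_LAW = ScalingLaw(prefactor=0.19, exponent=0.588)

#: Nucleosome diameter from the crystal-structure disk, nm.
NUCLEOSOME_DIAMETER = 11.0

PROTEIN_CONFORMATIONS = ("predicted", "relaxed", "expanded")
RNA_CONFORMATIONS = ("folded", "relaxed", "expanded")


@dataclass(frozen=True)
class MoleculeGeometry:
    """Diameter and pervaded (spherical) volume of one species in one
    conformation."""

    species: str
    conformation: str
    diameter: float  # nm

    @property
    def volume(self) -> float:
        """Pervaded volume, nm³."""
        return molecule_volume(self.diameter)


def segment_domains(flags: str | Sequence[str], window: int = 5) -> list[DomainSegment]:
    """Partition per-residue order flags into ordered/disordered domains.

    ``flags`` is a sequence of 'O' (ordered) / 'D' (disordered). A
    centered majority window of ``window`` residues smooths the flags
    (ties and edge truncation resolve to ordered); runs shorter than
    ``window`` are then absorbed into their flanks until every domain
    has at least ``window`` residues (or a single domain remains).
    Segment radii of gyration are left unset.
    """
    seq = list(flags)
    if not seq:
        raise ValueError("per-residue flags must be non-empty")
    if any(f not in ("O", "D") for f in seq):
        raise ValueError("flags must be 'O' or 'D'")
    half = window // 2
    n = len(seq)
    smoothed = []
    for i in range(n):
        win = seq[max(0, i - half) : min(n, i + half + 1)]
        d = win.count("D")
        smoothed.append("D" if d > len(win) - d else "O")

    runs: list[list] = []  # [kind, length]
    for f in smoothed:
        if runs and runs[-1][0] == f:
            runs[-1][1] += 1
        else:
            runs.append([f, 1])
    # absorb short runs (shortest first) into their flanks; flanking runs
    # of a binary alternation share the opposite kind, so absorbing a run
    # merges it with both neighbours
    while len(runs) > 1:
        shortest = min(range(len(runs)), key=lambda i: (runs[i][1], i))
        if runs[shortest][1] >= window:
            break
        kind, length = runs.pop(shortest)
        if 0 < shortest < len(runs):
            # interior: merge previous, absorbed, next into one run
            prev = runs[shortest - 1]
            nxt = runs.pop(shortest)
            prev[1] += length + nxt[1]
        elif shortest == 0:
            runs[0][1] += length
        else:
            runs[-1][1] += length
    return [
        DomainSegment(kind="ordered" if k == "O" else "disordered", n_residues=ln)
        for k, ln in runs
    ]


def rg_disordered(n_residues: int, law: ScalingLaw = DISORDERED_RG_LAW) -> float:
    """Radius of gyration (nm) of a disordered stretch of ``n_residues``."""
    return law.rg(n_residues)


def resolve_domain_rgs(
    domains: Sequence[DomainSegment], law: ScalingLaw = DISORDERED_RG_LAW
) -> list[DomainSegment]:
    """Fill unset radii of gyration from the disordered scaling law.

    Ordered domains must carry a structure-derived Rg; an ordered domain
    with no Rg is an error.
    """
    resolved = []
    for d in domains:
        if d.rg is not None:
            resolved.append(d)
        elif d.kind == "disordered":
            resolved.append(DomainSegment(kind=d.kind, n_residues=d.n_residues, rg=law.rg(d.n_residues)))
        else:
            raise ValueError(
                f"ordered domain of {d.n_residues} residues has no radius of gyration"
            )
    return resolved


def _rgs(domains: Sequence[DomainSegment]) -> list[float]:
    if not domains:
        raise ValueError("at least one domain is required")
    rgs = []
    for d in domains:
        if d.rg is None:
            raise ValueError("domain missing radius of gyration; resolve_domain_rgs first")
        rgs.append(d.rg)
    return rgs


def diameter_relaxed(domains: Sequence[DomainSegment], predicted_diameter: float) -> float:
    """Random-walk diameter over domains, floored at the predicted one.

    d = 2·sqrt(Σ Rg_i²); the floor covers compact proteins whose
    predicted structure already pervades more space than the walk.
    """
    rgs = _rgs(domains)
    d = 2.0 * math.sqrt(sum(r * r for r in rgs))
    return max(d, predicted_diameter)


def diameter_expanded(
    domains: Sequence[DomainSegment],
    predicted_diameter: float,
    denatured_diameter: float,
) -> float:
    """Expanded diameter: midpoint of straight-line and random-walk
    domain arrangements, capped at the fully denatured chain.

    d = Σ Rg_i + sqrt(Σ Rg_i²), then min with ``denatured_diameter`` and
    floored at the relaxed diameter so conformation sizes stay ordered.
    """
    rgs = _rgs(domains)
    root = math.sqrt(sum(r * r for r in rgs))
    d = sum(rgs) + root
    d = min(d, denatured_diameter)
    return max(d, diameter_relaxed(domains, predicted_diameter))


def protein_diameters(
    species: ProteinSpecies,
    disordered_law: ScalingLaw = DISORDERED_RG_LAW,
    denatured_law: ScalingLaw = DENATURED_RG_LAW,
) -> dict[str, float]:
    """Predicted/relaxed/expanded diameters (nm) for one protein.

    A species without a domain decomposition (e.g. a preassembled
    complex whose sizes are direct inputs) keeps its predicted diameter
    in all three conformations.
    """
    if not species.domains:
        d = species.predicted_diameter
        return {"predicted": d, "relaxed": d, "expanded": d}
    domains = resolve_domain_rgs(species.domains, disordered_law)
    total_residues = sum(d.n_residues for d in domains)
    denatured = 2.0 * denatured_law.rg(total_residues)
    relaxed = diameter_relaxed(domains, species.predicted_diameter)
    expanded = diameter_expanded(domains, species.predicted_diameter, denatured)
    return {
        "predicted": species.predicted_diameter,
        "relaxed": relaxed,
        "expanded": expanded,
    }


def rna_diameter(n_nt: float, conformation: str) -> float:
    """RNA diameter (nm) for a chain of ``n_nt`` nucleotides.

    folded: 2·0.55·N^0.33 (scaling law over solved RNA structures);
    expanded: twice the worm-like-chain radius of gyration with
    l_p = 0.15·N^0.33 nm and l_c = 0.696 nm·N;
    relaxed: arithmetic mean of the two.
    """
    if n_nt < 1:
        raise ValueError("RNA length must be >= 1 nt")
    if conformation in ("folded", "predicted"):
        return 2.0 * 0.55 * n_nt**0.33
    if conformation == "expanded":
        lp = 0.15 * n_nt**0.33
        lc = 0.696 * n_nt
        rg_sq = (
            lp * lc / 3.0
            - lp * lp
            + 2.0 * lp**3 / lc * (1.0 - lp / lc * (1.0 - math.exp(-lc / lp)))
        )
        return 2.0 * math.sqrt(rg_sq)
    if conformation == "relaxed":
        return 0.5 * (rna_diameter(n_nt, "folded") + rna_diameter(n_nt, "expanded"))
    raise ValueError(f"unknown RNA conformation {conformation!r}")


def molecule_volume(diameter: float) -> float:
    """Pervaded spherical volume (nm³) of a molecule of ``diameter`` nm."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return (4.0 * math.pi / 3.0) * (diameter / 2.0) ** 3
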