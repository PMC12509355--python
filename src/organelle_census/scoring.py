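"""Debye-length scoring, mechanism classification, and virtual-microscopy
rendering.

The score maps an intermolecular surface distance Δ onto [0, 1]:
S_D = 1 for Δ < λ_D and exp(−(Δ−λ_D)/λ_D) otherwise, with λ_D the
estimated maximum in-cell Debye length (2.2 nm). Distances within the
Debye length permit multivalent interaction networks (PSCP/LLPS); an
organelle whose three multicomponent scenarios all score below the
cutoff is better explained by binding to clustered chromatin sites
(ICBS).
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from ._units import AVOGADRO, LITRES_PER_UM3, NM3_PER_UM3
from .conformers import MoleculeGeometry
from .model_io import CensusEntry, ScoreCard

__all__ = [
    "sd_score",
    "classify",
    "score_card",
    "nucleosome_protein_ratio",
    "sample_voxel_counts",
    "render_voxel",
]

DEFAULT_DEBYE_LENGTH = 2.2  # nm
DEFAULT_CUTOFF = 0.5


def sd_score(delta: float, lambda_d: float = DEFAULT_DEBYE_LENGTH) -> float:
    """Debye-length score of a surface-to-surface distance (nm).

    Continuous and non-increasing in Δ; equals 1 on [0, λ_D] and decays
    exponentially with decay length λ_D beyond.
    """
    if delta < 0:
        raise ValueError("distance must be >= 0")
    if lambda_d <= 0:
        raise ValueError("lambda_d must be positive")
    if delta < lambda_d:
        return 1.0
    return math.exp(-(delta - lambda_d) / lambda_d)


def classify(scores: Mapping[str, float], cutoff: float = DEFAULT_CUTOFF) -> tuple[str, tuple[str, ...]]:
    """Mechanism call from the three scenario scores.

    Returns ``(call, passing_scenarios)``: compatible with PSCP/LLPS if
    any scenario scores at or above the cutoff, otherwise ICBS is
    favored.
    """
    passing = tuple(name for name, s in scores.items() if s >= cutoff)
    call = "PSCP_LLPS_compatible" if passing else "ICBS_favored"
    return call, passing


def nucleosome_protein_ratio(entries: Sequence[CensusEntry], organelle: str) -> float:
    """Nucleosomes per candidate scaffold protein copy in one organelle."""
    nucleosomes = sum(
        e.copies_in_organelle
        for e in entries
        if e.organelle == organelle and e.species_class == "nucleosome"
    )
    proteins = sum(
        e.copies_in_organelle
        for e in entries
        if e.organelle == organelle and e.species_class == "protein"
    )
    if proteins <= 0:
        raise ValueError(f"no candidate scaffold proteins in organelle {organelle!r}")
    return nucleosomes / proteins


def score_card(
    organelle: str,
    surface_distances: Mapping[str, float],
    entries: Sequence[CensusEntry],
    lambda_d: float = DEFAULT_DEBYE_LENGTH,
    cutoff: float = DEFAULT_CUTOFF,
) -> ScoreCard:
    """Build a :class:`ScoreCard` from per-scenario surface distances."""
    scores = {name: sd_score(d, lambda_d) for name, d in surface_distances.items()}
    call, passing = classify(scores, cutoff)
    return ScoreCard(
        organelle=organelle,
        scores=scores,
        nucleosome_to_protein_ratio=nucleosome_protein_ratio(entries, organelle),
        mechanism_call=call,
        cutoff=cutoff,
        passing_scenarios=passing,
    )


# ---------------------------------------------------------------------------
# virtual microscopy


_CLASS_COLORS = {
    "nucleosome": (150, 150, 150),
    "rna": (139, 0, 0),
}
_PROTEIN_PALETTE = [
    (230, 159, 0),
    (86, 180, 233),
    (0, 158, 115),
    (240, 228, 66),
    (0, 114, 178),
    (213, 94, 0),
    (204, 121, 167),
]


def sample_voxel_counts(
    entries: Sequence[CensusEntry],
    organelle: str,
    voxel_radius: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Poisson-sample per-species molecule counts for one voxel.

    The voxel is a sphere of ``voxel_radius`` nm; each species'
    expected count is its organelle concentration times the voxel
    volume.
    """
    v_voxel_l = (4.0 * math.pi / 3.0) * voxel_radius**3 / NM3_PER_UM3 * LITRES_PER_UM3
    counts = {}
    for e in entries:
        if e.organelle != organelle:
            continue
        lam = e.concentration * 1.0e-6 * AVOGADRO * v_voxel_l
        counts[e.species] = int(rng.poisson(lam))
    return counts


def _place_spheres(
    n: int,
    radius: float,
    voxel_radius: float,
    occupied: list[tuple[float, float, float, float]],
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> list[tuple[float, float, float]]:
    """Uniform positions in the voxel sphere with hard-sphere rejection.

    Falls back to allowing overlap once the attempt budget per molecule
    is exhausted.
    """
    placed = []
    for _ in range(n):
        pos = None
        for _attempt in range(max_attempts):
            p = rng.uniform(-voxel_radius, voxel_radius, size=3)
            if float(np.dot(p, p)) > voxel_radius**2:
                continue
            ok = True
            for (x, y, z, r2) in occupied:
                dx, dy, dz = p[0] - x, p[1] - y, p[2] - z
                if dx * dx + dy * dy + dz * dz < (radius + r2) ** 2:
                    ok = False
                    break
            if ok:
                pos = p
                break
        if pos is None:  # budget exhausted: accept the last in-sphere draw
            while True:
                p = rng.uniform(-voxel_radius, voxel_radius, size=3)
                if float(np.dot(p, p)) <= voxel_radius**2:
                    pos = p
                    break
        occupied.append((float(pos[0]), float(pos[1]), float(pos[2]), radius))
        placed.append((float(pos[0]), float(pos[1]), float(pos[2])))
    return placed


def render_voxel(
    entries: Sequence[CensusEntry],
    geometries: Mapping[tuple[str, str], MoleculeGeometry],
    organelle: str,
    voxel_radius: float = 250.0,
    seed: int = 0,
    conformation: str = "predicted",
    image_size: int = 500,
) -> Image.Image:
    """Render one confocal-pixel volume of an organelle to scale.

    Molecules are Poisson-sampled at their organelle concentrations and
    placed uniformly at random (hard-sphere rejection with a bounded
    attempt budget) in a sphere of ``voxel_radius`` nm, then projected
    orthographically. Nucleosomes are gray, RNAs dark red, proteins take
    per-species palette colors. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    counts = sample_voxel_counts(entries, organelle, voxel_radius, rng)
    img = Image.new("RGB", (image_size, image_size), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    scale = image_size / (2.0 * voxel_radius)

    by_class = {e.species: e.species_class for e in entries if e.organelle == organelle}
    protein_names = sorted(n for n, c in by_class.items() if c == "protein")
    palette = {
        name: _PROTEIN_PALETTE[i % len(_PROTEIN_PALETTE)]
        for i, name in enumerate(protein_names)
    }

    occupied: list[tuple[float, float, float, float]] = []
    drawn = []  # (z, x, y, radius_nm, color)
    # nucleosomes first, then RNAs, then proteins, as in the class layering
    ordering = {"nucleosome": 0, "rna": 1, "protein": 2}
    for species in sorted(counts, key=lambda s: (ordering[by_class[s]], s)):
        cls = by_class[species]
        conf = ("folded" if conformation == "predicted" else conformation) if cls == "rna" else conformation
        geom = geometries.get((species, conf))
        if geom is None:
            raise KeyError(f"no geometry for species {species!r} conformation {conf!r}")
        color = _CLASS_COLORS.get(cls) or palette[species]
        for (x, y, z) in _place_spheres(
            counts[species], geom.diameter / 2.0, voxel_radius, occupied, rng
        ):
            drawn.append((z, x, y, geom.diameter / 2.0, color))
    # painter's algorithm: far-to-near along the projection axis
    for z, x, y, r, color in sorted(drawn, key=lambda t: t[0]):
        cx = (x + voxel_radius) * scale
        cy = (y + voxel_radius) * scale
        rr = max(r * scale, 0.5)
        draw.ellipse([cx - rr, cy - rr, cx + rr, cy + rr], fill=color)
    return img
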