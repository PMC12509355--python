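"""Synthetic cells with known ground truth, and Monte-Carlo oracles.

The generator emulates the study conditions of the census workflow: a
diploid mESC-like nucleus hosting a nucleolus-like organelle class and a
heterochromatin-focus-like class, with candidate scaffold abundances
spanning the proteome-wide range (log-uniform 10³–10⁷ copies), iBAQ
intensities proportional to copies up to mean-one lognormal noise, and
per-species organelle enrichments. Everything is written/read through
the public configuration dialects, so the generator doubles as an
end-to-end test fixture.

The Monte-Carlo oracles provide independent estimates of mean nearest-
neighbor distances: an ideal-gas (Poisson) point process, and random
sequential insertion of hard spheres. Both use periodic boundaries to
avoid edge bias.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model_io import (
    CalibrationRef,
    CellConfig,
    DomainSegment,
    NucleusModel,
    OrganelleModel,
    ProteinSpecies,
    write_config,
    write_species_tsv,
)

__all__ = [
    "SyntheticTruth",
    "make_synthetic_cell",
    "poisson_nn_oracle",
    "hard_sphere_nn_oracle",
]

#: Default true iBAQ→copies scale (arbitrary linear iBAQ units).
DEFAULT_SCALE_A = 150.0

#: Anchor proteins mirroring the six experimentally counted references.
_N_CALIBRATION_REFS = 6

_DEFAULT_ORGANELLES = (
    dict(
        name="nucleolus_gc",
        volume=30.0,
        count_per_nucleus=2,
        rna_enrichment=5.0,
        nucleosome_enrichment=0.3,
        rna_length=14000.0,
        dapi_bias_correction=False,
    ),
    dict(
        name="heterochromatin_foci",
        volume=5.0,
        count_per_nucleus=10,
        rna_enrichment=0.5,
        nucleosome_enrichment=3.0,
        rna_length=2790.0,
        dapi_bias_correction=True,
    ),
)

_DEFAULT_NUCLEUS_VOLUME = 450.0  # µm³, mESC-like


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a synthetic cell."""

    scale_a: float
    total_copies: Mapping[str, float]  # species -> true whole-cell copies
    enrichments: Mapping[str, float]  # species -> true α


def _random_domains(rng: np.random.Generator, n_residues: int) -> tuple[DomainSegment, ...]:
    # 1–4 alternating ordered/disordered stretches, each >= 5 residues;
    # ordered segments carry a compact-globule Rg, disordered ones derive
    # theirs from the scaling law at load time
    n_domains = int(rng.integers(1, 5))
    n_domains = min(n_domains, n_residues // 5) or 1
    cuts = np.sort(rng.choice(np.arange(1, max(n_residues // 5, 2)), size=n_domains - 1, replace=False)) * 5 if n_domains > 1 else np.array([], dtype=int)
    lengths = np.diff(np.concatenate([[0], cuts, [n_residues]]))
    start_kind = rng.integers(0, 2)
    segments = []
    for i, ln in enumerate(lengths):
        ln = int(ln)
        if ln < 1:
            continue
        if (i + start_kind) % 2 == 0:
            rg = 0.22 * ln**0.38  # compact folded-domain scaling, nm
            segments.append(DomainSegment(kind="ordered", n_residues=ln, rg=rg))
        else:
            segments.append(DomainSegment(kind="disordered", n_residues=ln, rg=None))
    return tuple(segments)


def make_synthetic_cell(
    seed: int,
    n_species: int = 12,
    organelle_specs: Sequence[dict] | None = None,
    noise_sigma: float = 0.0,
    scale_a: float = DEFAULT_SCALE_A,
    infinite_alpha_fraction: float = 0.1,
    out_dir: str | Path | None = None,
) -> tuple[CellConfig, SyntheticTruth]:
    """Generate a cell model with known ground truth.

    True whole-cell copies are log-uniform on 10³–10⁷; iBAQ values are
    ``copies/scale_a`` times mean-one lognormal noise of width
    ``noise_sigma``; enrichments α are log-uniform on 0.2–20 with a
    fraction of exclusively localized species (α = ∞). If ``out_dir``
    is given, a ``config.yaml`` and ``species.tsv`` are written in the
    public dialects (byte-identical for a fixed seed).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    organelles = tuple(
        OrganelleModel(**spec) for spec in (organelle_specs or _DEFAULT_ORGANELLES)
    )
    nucleus = NucleusModel(nucleus_volume=_DEFAULT_NUCLEUS_VOLUME)

    def noisy(x: float) -> float:
        if noise_sigma == 0.0:
            return x
        return x * float(
            np.exp(rng.normal(-0.5 * noise_sigma**2, noise_sigma))
        )

    species = []
    copies: dict[str, float] = {}
    alphas: dict[str, float] = {}
    for i in range(n_species):
        name = f"protein_{i:03d}"
        n_tot = float(10 ** rng.uniform(3, 7))
        if rng.uniform() < infinite_alpha_fraction:
            alpha = math.inf
        else:
            alpha = float(10 ** rng.uniform(math.log10(0.2), math.log10(20.0)))
        n_residues = int(rng.integers(100, 1500))
        mw = n_residues * 110.0  # average residue mass, g/mol
        domains = _random_domains(rng, n_residues)
        predicted_diameter = 2.0 * 0.22 * n_residues**0.38
        species.append(
            ProteinSpecies(
                name=name,
                mw=mw,
                predicted_diameter=predicted_diameter,
                ibaq=noisy(n_tot / scale_a),
                enrichment=alpha,
                domains=domains,
            )
        )
        copies[name] = n_tot
        alphas[name] = alpha

    refs = []
    for i in range(_N_CALIBRATION_REFS):
        n_ref = float(10 ** rng.uniform(4, 7))
        refs.append(
            CalibrationRef(
                protein=f"anchor_{i}",
                measured_copies=n_ref,
                ibaq=noisy(n_ref / scale_a),
            )
        )

    config = CellConfig(
        nucleus=nucleus,
        organelles=organelles,
        species=tuple(species),
        calibration_refs=tuple(refs),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_config(config, out_dir / "config.yaml")
        write_species_tsv(species, out_dir / "species.tsv")
    return config, SyntheticTruth(scale_a=scale_a, total_copies=copies, enrichments=alphas)


def poisson_nn_oracle(density: float, n_points: int, seed: int) -> float:
    """Mean nearest-neighbor center distance of an ideal-gas point process.

    Samples ``n_points`` uniform points in a periodic cube at the given
    number density (nm⁻³). The analytic expectation is
    Γ(4/3)·(4π·density/3)^{−1/3} ≈ 0.55396·density^{−1/3}.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    side = (n_points / density) ** (1.0 / 3.0)
    points = rng.uniform(0.0, side, size=(n_points, 3))
    tree = cKDTree(points, boxsize=side)
    dists, _ = tree.query(points, k=2)
    return float(dists[:, 1].mean())


def hard_sphere_nn_oracle(
    r: float,
    phi: float,
    n_points: int,
    seed: int,
    max_attempts_per_point: int = 2000,
) -> float:
    """Mean nearest-neighbor center distance of non-overlapping spheres.

    Random sequential insertion of ``n_points`` spheres of radius ``r``
    at volume fraction ``phi`` in a periodic cube. Feasible for
    φ ≲ 0.3 (well below the ~0.38 insertion jamming limit).
    """
    if not 0 < phi <= 0.3:
        raise ValueError("phi must lie in (0, 0.3] for sequential insertion")
    rng = np.random.default_rng(seed)
    sphere_volume = (4.0 * math.pi / 3.0) * r**3
    side = (n_points * sphere_volume / phi) ** (1.0 / 3.0)
    min_sq = (2.0 * r) ** 2
    accepted = np.empty((n_points, 3))
    n_acc = 0
    budget = max_attempts_per_point * n_points
    while n_acc < n_points:
        if budget <= 0:
            raise RuntimeError(
                "sphere insertion budget exhausted; lower phi or n_points"
            )
        candidate = rng.uniform(0.0, side, size=3)
        if n_acc:
            delta = np.abs(accepted[:n_acc] - candidate)
            delta = np.minimum(delta, side - delta)  # periodic minimum image
            if np.min(np.einsum("ij,ij->i", delta, delta)) < min_sq:
                budget -= 1
                continue
        accepted[n_acc] = candidate
        n_acc += 1
        budget -= 1
    tree = cKDTree(accepted, boxsize=side)
    dists, _ = tree.query(accepted, k=2)
    return float(dists[:, 1].mean())
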