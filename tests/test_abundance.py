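"""Calibration, partitioning, RNA/nucleosome pools and mass densities."""
import math

import numpy as np
import pytest

from organelle_census import (
    CalibrationRef,
    CensusEntry,
    NucleusModel,
    OrganelleModel,
    dna_content,
    enrichment_from_intensities,
    expected_satellite_dna,
    fit_calibration,
    mass_density,
    nucleosome_census,
    organelle_copies,
    rna_census,
    theoretical_h4_total,
    total_copies,
)
from organelle_census.abundance import nucleosome_mw
from organelle_census.model_io import ProteinSpecies


class TestH4Total:
    def test_diploid_defaults_give_about_54_million(self, nucleus):
        total = theoretical_h4_total(nucleus)
        assert total == pytest.approx(4 * 2.5e9 / 186)
        assert round(total / 1e6) == 54

    def test_haploid_is_half_of_diploid(self, nucleus):
        haploid = NucleusModel(nucleus_volume=450.0, ploidy=1)
        assert theoretical_h4_total(haploid) == theoretical_h4_total(nucleus) / 2

    def test_repeat_length_200(self):
        nuc = NucleusModel(nucleus_volume=450.0, nucleosome_repeat_length=200.0)
        assert theoretical_h4_total(nuc) == pytest.approx(5.0e7)


class TestCalibration:
    @pytest.mark.parametrize(
        "refs, slope",
        [
            ([(1000.0, 10.0)], 100.0),
            ([(100.0, 1.0), (200.0, 2.0)], 100.0),
            ([(100.0, 1.0), (300.0, 2.0)], 140.0),  # Σxy/Σx² = 700/5
        ],
    )
    def test_through_origin_slope(self, refs, slope):
        model = fit_calibration(
            [CalibrationRef(f"p{i}", copies, ibaq) for i, (copies, ibaq) in enumerate(refs)]
        )
        assert model.scale_a == pytest.approx(slope)

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            CalibrationRef("p", -5.0, 1.0)

    def test_noise_free_synthetic_refs_recover_slope_exactly(self):
        rng = np.random.default_rng(0)
        a_true = 137.5
        copies = 10 ** rng.uniform(3, 7, size=8)
        refs = [CalibrationRef(f"p{i}", c, c / a_true) for i, c in enumerate(copies)]
        model = fit_calibration(refs)
        assert model.scale_a == pytest.approx(a_true, rel=1e-12)
        assert model.stderr == pytest.approx(0.0, abs=1e-6)


class TestTotalCopies:
    def _species(self, **kw):
        base = dict(name="p", mw=5e4, predicted_diameter=4.0)
        base.update(kw)
        return ProteinSpecies(**base)

    def test_undetected_protein_gets_detection_limit(self, nucleus):
        sp = self._species(ibaq=0.0)
        assert total_copies(sp, None, nucleus) == 407.0

    def test_ibaq_path(self, nucleus):
        sp = self._species(ibaq=10.0)
        calib = fit_calibration([CalibrationRef("a", 1000.0, 10.0)])
        assert total_copies(sp, calib, nucleus) == pytest.approx(1000.0)

    def test_direct_copies_override(self, nucleus):
        sp = self._species(total_copies=5e4)
        assert total_copies(sp, None, nucleus) == 5e4


class TestEnrichment:
    def test_background_subtraction(self):
        assert enrichment_from_intensities(30.0, 12.0, 2.0) == pytest.approx(2.8)

    def test_no_enrichment(self):
        assert enrichment_from_intensities(12.0, 12.0, 2.0) == pytest.approx(1.0)

    def test_full_depletion(self):
        assert enrichment_from_intensities(2.0, 12.0, 2.0) == pytest.approx(0.0)

    def test_background_above_nucleoplasm_rejected(self):
        with pytest.raises(ValueError):
            enrichment_from_intensities(30.0, 2.0, 12.0)


class TestOrganellePartition:
    def test_uniform_alpha_distributes_by_volume(self, nucleus, focus):
        n_org, _ = organelle_copies(1e6, 1.0, focus, nucleus)
        assert n_org == pytest.approx(1e6 * focus.volume / nucleus.nucleus_volume)

    def test_exclusive_localization_splits_over_organelles(self, nucleus, focus):
        n_org, _ = organelle_copies(1e6, math.inf, focus, nucleus)
        assert n_org == pytest.approx(1e6 / focus.count_per_nucleus)

    def test_worked_partition(self):
        nuc = NucleusModel(nucleus_volume=100.0)
        org = OrganelleModel(name="o", volume=1.0, count_per_nucleus=10)
        n_org, _ = organelle_copies(1e6, 10.0, org, nuc)
        assert n_org == pytest.approx(1e7 / 190)

    def test_conservation_for_random_geometries(self, nucleus):
        rng = np.random.default_rng(42)
        for _ in range(50):
            v_org = rng.uniform(0.5, 20.0)
            n = int(rng.integers(1, 12))
            while n * v_org >= nucleus.nucleus_volume:
                v_org /= 2
            alpha = 10 ** rng.uniform(-2, 2)
            org = OrganelleModel(name="o", volume=v_org, count_per_nucleus=n)
            n_tot = 10 ** rng.uniform(3, 7)
            n_org, c_org_um = organelle_copies(n_tot, alpha, org, nucleus)
            denom = (alpha - 1) * n * v_org + nucleus.nucleus_volume
            c_np = n_tot / denom  # copies per µm³, from the same algebra
            v_np = nucleus.nucleus_volume - n * v_org
            assert n * n_org + c_np * v_np == pytest.approx(n_tot, rel=1e-9)

    def test_copies_increase_with_enrichment(self, nucleus, focus):
        values = [organelle_copies(1e6, a, focus, nucleus)[0] for a in (0.5, 1, 2, 5, 50)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_infinite_alpha_matches_numeric_limit(self, nucleus, focus):
        exact, _ = organelle_copies(1e6, math.inf, focus, nucleus)
        numeric, _ = organelle_copies(1e6, 1e9, focus, nucleus)
        assert numeric == pytest.approx(exact, rel=1e-6)


class TestRnaCensus:
    def test_total_ribonucleotide_budget(self, nucleus, focus):
        pool = rna_census(nucleus, [focus])
        expected = 20e-12 * 0.15 / 340 * 6.02214076e23
        assert pool.total_ribonucleotides == pytest.approx(expected)
        assert pool.total_ribonucleotides == pytest.approx(5.31e9, rel=5e-3)

    def test_uniform_enrichment_gives_uniform_concentration(self, nucleus):
        orgs = [
            OrganelleModel(name="a", volume=10.0, count_per_nucleus=2, rna_enrichment=1.0),
            OrganelleModel(name="b", volume=1.0, count_per_nucleus=5, rna_enrichment=1.0),
        ]
        pool = rna_census(nucleus, orgs)
        for org in orgs:
            c_org = pool.per_organelle_ribonucleotides[org.name] / org.volume
            assert c_org == pytest.approx(pool.nucleoplasm_concentration, rel=1e-12)

    def test_zero_enrichment_keeps_all_rna_in_nucleoplasm(self, nucleus):
        org = OrganelleModel(name="a", volume=10.0, rna_enrichment=0.0)
        pool = rna_census(nucleus, [org])
        assert pool.per_organelle_ribonucleotides["a"] == 0.0
        assert pool.nucleoplasm_ribonucleotides == pytest.approx(
            pool.total_ribonucleotides, rel=1e-12
        )

    def test_ribonucleotide_conservation(self, nucleus):
        rng = np.random.default_rng(3)
        orgs = [
            OrganelleModel(
                name=f"o{i}",
                volume=rng.uniform(0.5, 15.0),
                count_per_nucleus=int(rng.integers(1, 8)),
                rna_enrichment=10 ** rng.uniform(-1.5, 1.5),
            )
            for i in range(4)
        ]
        pool = rna_census(nucleus, orgs)
        total = pool.nucleoplasm_ribonucleotides + sum(
            o.count_per_nucleus * pool.per_organelle_ribonucleotides[o.name] for o in orgs
        )
        assert total == pytest.approx(pool.total_ribonucleotides, rel=1e-9)


class TestNucleosomeCensus:
    def test_two_h4_per_nucleosome(self, nucleus):
        org = OrganelleModel(name="all", volume=449.0, nucleosome_enrichment=1.0)
        nucleosomes = nucleosome_census(nucleus, org, 54e6)
        # α = 1: organelle share is its volume fraction of the nucleus
        assert nucleosomes == pytest.approx(27e6 * 449.0 / 450.0)

    def test_dapi_bias_divides_enrichment(self, nucleus):
        biased = OrganelleModel(
            name="o", volume=5.0, nucleosome_enrichment=3.0, dapi_bias_correction=True
        )
        unbiased = OrganelleModel(name="o", volume=5.0, nucleosome_enrichment=2.0)
        assert nucleosome_census(nucleus, biased, 54e6) == pytest.approx(
            nucleosome_census(nucleus, unbiased, 54e6)
        )

    def test_uniform_distribution_fraction(self):
        nuc = NucleusModel(nucleus_volume=100.0)
        org = OrganelleModel(name="o", volume=1.0, nucleosome_enrichment=1.0)
        assert nucleosome_census(nuc, org, 54e6) == pytest.approx(0.01 * 27e6)


class TestDnaContent:
    def test_heterochromatin_focus_scale(self, nucleus):
        assert dna_content(180_000, nucleus) == pytest.approx(33.48e6)

    def test_polycomb_body_scale(self, nucleus):
        assert dna_content(1400, nucleus) == pytest.approx(260.4e3)

    def test_zero(self, nucleus):
        assert dna_content(0, nucleus) == 0.0

    def test_expected_satellite_dna(self, nucleus):
        # ploidy × 2.5 Gb × 3% / 66% ≈ 230 Mb
        assert expected_satellite_dna(nucleus) == pytest.approx(227.27e6, rel=1e-3)


class TestMassDensity:
    def test_single_species_density(self):
        org = OrganelleModel(name="o", volume=1.0)
        entries = [CensusEntry("p", "protein", "o", 1e6, 0.0, 0.0)]
        density = mass_density(entries, org, {"p": 6e4})
        assert density["protein"] == pytest.approx(99.6, rel=1e-2)

    def test_empty_class_is_zero(self):
        org = OrganelleModel(name="o", volume=1.0)
        entries = [CensusEntry("p", "protein", "o", 1e6, 0.0, 0.0)]
        assert mass_density(entries, org, {"p": 6e4})["rna"] == 0.0

    def test_doubling_volume_halves_density(self):
        small = OrganelleModel(name="o", volume=1.0)
        big = OrganelleModel(name="o", volume=2.0)
        entries = [CensusEntry("p", "protein", "o", 1e6, 0.0, 0.0)]
        d1 = mass_density(entries, small, {"p": 6e4})["protein"]
        d2 = mass_density(entries, big, {"p": 6e4})["protein"]
        assert d2 == pytest.approx(d1 / 2)

    def test_missing_mw_names_species(self):
        org = OrganelleModel(name="o", volume=1.0)
        entries = [CensusEntry("mystery", "protein", "o", 1.0, 0.0, 0.0)]
        with pytest.raises(ValueError, match="mystery"):
            mass_density(entries, org, {})

    def test_nucleosome_mw_default(self, nucleus):
        assert nucleosome_mw(nucleus) == pytest.approx(108_000 + 186 * 650)
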