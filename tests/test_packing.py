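"""Hard-sphere crowding metrics and nearest-neighbor distances."""
import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from organelle_census import (
    CensusEntry,
    MixtureComponent,
    MoleculeGeometry,
    available_volume,
    effective_radius,
    nn_center_distance,
    nn_surface_distance,
    overlap_ratio,
    scenario_distances,
    volume_fraction,
)
from organelle_census.packing import RANDOM_CLOSE_PACKING, components_for_scenario


class TestAvailableVolume:
    def test_one_cubic_micron_million_molecules(self):
        assert available_volume(1.0, 1e6) == pytest.approx(1000.0)

    def test_halving_copies_doubles_volume(self):
        assert available_volume(1.0, 5e5) == pytest.approx(2 * available_volume(1.0, 1e6))

    def test_worked_value(self):
        assert available_volume(0.1, 2.5e4) == pytest.approx(4000.0)

    def test_zero_molecules_rejected(self):
        with pytest.raises(ValueError):
            available_volume(1.0, 0)


class TestVolumeFraction:
    def test_sphere_filling_its_available_volume(self):
        assert volume_fraction(1.0, 4 * math.pi / 3) == pytest.approx(1.0)

    def test_dilute_value(self):
        assert volume_fraction(1.0, 4188.790205) == pytest.approx(1e-3, rel=1e-6)

    def test_cubic_scaling(self):
        assert volume_fraction(2.0, 1000.0) == pytest.approx(8 * volume_fraction(1.0, 1000.0))


class TestNearestNeighborDistance:
    def test_dilute_limit_value(self):
        # frozen from the analytic expression; agrees with the Poisson
        # point-process mean 0.55396·n^(-1/3) to 0.1%
        assert nn_center_distance(1.0, 1e-6) == pytest.approx(89.2987, rel=1e-4)
        n = 1e-6 / (4 * math.pi / 3)
        poisson = gamma_fn(4 / 3) * (4 * math.pi * n / 3) ** (-1 / 3)
        assert nn_center_distance(1.0, 1e-6) == pytest.approx(poisson, rel=2e-3)

    def test_small_phi_gamma_term_limit(self):
        # as φ → 0 the correction term approaches (Γ(1/3)/3)·r·φ^(-1/3)
        phi = 1e-12
        term = nn_center_distance(1.0, phi) - 2.0
        assert term == pytest.approx(gamma_fn(1 / 3) / 3 * phi ** (-1 / 3), rel=1e-3)

    def test_clamp_at_random_close_packing(self):
        assert nn_center_distance(1.0, RANDOM_CLOSE_PACKING) == pytest.approx(2.0)
        assert nn_surface_distance(1.0, 0.65) == 0.0
        assert nn_surface_distance(1.0, 0.9) == 0.0

    def test_surface_distance_strictly_decreasing_in_phi(self):
        grid = np.linspace(1e-4, 0.649, 200)
        values = [nn_surface_distance(1.0, phi) for phi in grid]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_continuous_up_to_clamp(self):
        # the analytic value itself is continuous; the clamp creates the
        # only discontinuity, at 0.65
        below = nn_surface_distance(1.0, 0.65 - 1e-9)
        assert below == pytest.approx(nn_center_distance(1.0, 0.65 - 1e-9) - 2.0)
        assert below > 0

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            nn_center_distance(1.0, 0.0)


class TestEffectiveRadius:
    def test_single_component_reduces_to_half_diameter(self):
        assert effective_radius([MixtureComponent("a", 5.0, 6.0)]) == pytest.approx(3.0)

    def test_equal_counts_third_moment_mean(self):
        comps = [MixtureComponent("a", 1.0, 2.0), MixtureComponent("b", 1.0, 4.0)]
        assert effective_radius(comps) == pytest.approx(4.5 ** (1 / 3))

    def test_invariant_under_duplication(self):
        comps = [MixtureComponent("a", 2.0, 2.0), MixtureComponent("b", 3.0, 5.0)]
        assert effective_radius(comps + comps) == pytest.approx(effective_radius(comps))

    def test_all_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            effective_radius([MixtureComponent("a", 0.0, 2.0)])


class TestOverlapRatio:
    def test_exact_fill_is_unity(self):
        # one species whose pervaded volumes tile the organelle exactly
        d = 10.0
        v_mol = 4 * math.pi / 3 * (d / 2) ** 3
        n = 1e9 / v_mol
        assert overlap_ratio([MixtureComponent("a", n, d)], 1.0) == pytest.approx(1.0)

    def test_empty_mixture_is_zero(self):
        assert overlap_ratio([], 1.0) == 0.0

    def test_worked_value(self):
        assert overlap_ratio([MixtureComponent("a", 1e6, 10.0)], 1.0) == pytest.approx(
            0.5236, rel=1e-3
        )


def _geometries(diams):
    return {
        (name, conf): MoleculeGeometry(name, conf, d)
        for (name, conf), d in diams.items()
    }


class TestScenarioDistances:
    entries = [
        CensusEntry("p1", "protein", "org", 1e5, 0.0, 0.0),
        CensusEntry("p2", "protein", "org", 3e4, 0.0, 0.0),
        CensusEntry("RNA_org", "rna", "org", 2e4, 0.0, 0.0),
        CensusEntry("nucleosome", "nucleosome", "org", 5e5, 0.0, 0.0),
    ]
    geometries = _geometries(
        {
            ("p1", "relaxed"): 8.0,
            ("p2", "relaxed"): 5.0,
            ("RNA_org", "relaxed"): 40.0,
            ("nucleosome", "relaxed"): 11.0,
        }
    )

    def test_single_species_reduces_to_one_component_path(self):
        entries = [CensusEntry("p1", "protein", "org", 1e5, 0.0, 0.0)]
        state = scenario_distances(
            entries, self.geometries, "proteins_only", "relaxed", "org", 1.0
        )
        r = 4.0
        phi = volume_fraction(r, available_volume(1.0, 1e5))
        assert state.effective_radius == r
        assert state.volume_fraction == phi
        assert state.center_distance == nn_center_distance(r, phi)
        assert state.surface_distance == nn_surface_distance(r, phi)

    def test_adding_rna_increases_crowding(self):
        proteins = scenario_distances(
            self.entries, self.geometries, "proteins_only", "relaxed", "org", 1.0
        )
        with_rna = scenario_distances(
            self.entries, self.geometries, "proteins_rna", "relaxed", "org", 1.0
        )
        assert with_rna.volume_fraction > proteins.volume_fraction
        assert with_rna.surface_distance < proteins.surface_distance

    def test_order_invariance(self):
        state = scenario_distances(
            self.entries, self.geometries, "proteins_rna_nucleosomes", "relaxed", "org", 1.0
        )
        shuffled = scenario_distances(
            list(reversed(self.entries)),
            self.geometries,
            "proteins_rna_nucleosomes",
            "relaxed",
            "org",
            1.0,
        )
        assert state.effective_radius == pytest.approx(shuffled.effective_radius, rel=1e-12)
        assert state.volume_fraction == pytest.approx(shuffled.volume_fraction, rel=1e-12)
        assert state.surface_distance == pytest.approx(shuffled.surface_distance, rel=1e-12)
        assert state.overlap_ratio == pytest.approx(shuffled.overlap_ratio, rel=1e-12)

    def test_empty_scenario_returns_zero_state_with_warning(self, caplog):
        entries = [CensusEntry("RNA_org", "rna", "org", 1e4, 0.0, 0.0)]
        import logging

        with caplog.at_level(logging.WARNING, logger="organelle_census"):
            state = scenario_distances(
                entries, self.geometries, "proteins_only", "relaxed", "org", 1.0
            )
        assert state.volume_fraction == 0.0
        assert math.isinf(state.surface_distance)
        assert any("no molecules" in rec.message for rec in caplog.records)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            components_for_scenario(self.entries, self.geometries, "everything", "relaxed", "org")

    def test_rna_predicted_maps_to_folded_geometry(self):
        geoms = _geometries(
            {("RNA_org", "folded"): 15.0, ("p1", "predicted"): 4.0, ("p2", "predicted"): 4.0, ("nucleosome", "predicted"): 11.0}
        )
        comps = components_for_scenario(
            self.entries, geoms, "proteins_rna", "predicted", "org"
        )
        rna = [c for c in comps if c.species == "RNA_org"]
        assert rna and rna[0].diameter == 15.0
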