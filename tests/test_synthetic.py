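"""Synthetic landscape and species generation: schedules, determinism, truth."""

import dataclasses

import numpy as np
import pytest

from autoredlist.fragmentation import label_fragments
from autoredlist.synthetic import (
    ScenarioSpec,
    canned_scenarios,
    generate_landcover,
    generate_elevation,
    generate_species,
)
from helpers import make_esh


def habitat_counts(lc):
    code = sorted(lc.legend)[0]
    return [int((lc.data[i] == code).sum()) for i in range(len(lc.years))]


class TestLandcover:
    def test_no_loss_keeps_all_years_identical(self):
        spec = ScenarioSpec(
            grid_rows=20, grid_cols=20, years=(2000, 2001, 2002),
            habitat_fraction_initial=1.0, annual_loss_rate=0.0,
            n_fragments_target=1,
        )
        lc = generate_landcover(spec)
        assert (lc.data == lc.data[0]).all()
        assert habitat_counts(lc) == [400, 400, 400]

    def test_loss_schedule_hits_rounded_targets(self):
        spec = ScenarioSpec(
            grid_rows=100, grid_cols=100, years=(2000, 2001, 2002),
            habitat_fraction_initial=0.5, annual_loss_rate=0.1,
        )
        lc = generate_landcover(spec)
        assert habitat_counts(lc) == [5000, 4500, 4050]  # round(5000·0.9²) = 4050

    @pytest.mark.parametrize("loss_mode", ["erode", "random"])
    def test_bit_identical_under_fixed_seed(self, loss_mode):
        spec = ScenarioSpec(
            grid_rows=40, grid_cols=40, years=tuple(range(2000, 2006)),
            habitat_fraction_initial=0.4, annual_loss_rate=0.05,
            seed=7, loss_mode=loss_mode,
        )
        a = generate_landcover(spec)
        b = generate_landcover(spec)
        assert np.array_equal(a.data, b.data)

    def test_fragment_count_matches_target(self):
        spec = ScenarioSpec(
            grid_rows=60, grid_cols=60, years=(2000,),
            habitat_fraction_initial=0.2, n_fragments_target=6,
        )
        lc = generate_landcover(spec)
        esh = make_esh(lc.data[0] == spec.habitat_code, cell_size=spec.cell_size)
        for adjacency in ("rook", "queen"):
            assert label_fragments(esh, 2000, adjacency).n_fragments == 6

    @pytest.mark.parametrize("loss_mode", ["erode", "random"])
    def test_habitat_area_nonincreasing(self, loss_mode):
        spec = ScenarioSpec(
            grid_rows=50, grid_cols=50, years=tuple(range(1992, 2016)),
            habitat_fraction_initial=0.6, annual_loss_rate=0.08,
            loss_mode=loss_mode, seed=3,
        )
        counts = habitat_counts(generate_landcover(spec))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_exhaustion_emits_zero_years_with_flag(self):
        spec = ScenarioSpec(
            grid_rows=20, grid_cols=20, years=tuple(range(2000, 2020)),
            habitat_fraction_initial=0.1, annual_loss_rate=0.5,
        )
        lc = generate_landcover(spec)
        assert habitat_counts(lc)[-1] == 0
        assert lc.meta["exhausted"]

    def test_scatter_layout_hits_exact_count(self):
        spec = ScenarioSpec(
            grid_rows=50, grid_cols=50, years=(2000,), layout="scatter",
            habitat_fraction_initial=0.13, seed=11,
        )
        assert habitat_counts(generate_landcover(spec)) == [round(0.13 * 2500)]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="legend"):
            generate_landcover(dataclasses.replace(ScenarioSpec(), legend=()))
        with pytest.raises(ValueError, match="years"):
            generate_landcover(dataclasses.replace(ScenarioSpec(), years=(2001, 2000)))
        with pytest.raises(ValueError):
            generate_landcover(
                dataclasses.replace(ScenarioSpec(), habitat_fraction_initial=1.4)
            )

    def test_elevation_spans_requested_range_smoothly(self):
        spec = ScenarioSpec(grid_rows=40, grid_cols=40, years=(2000,),
                            elevation_range=1200.0)
        dem = generate_elevation(spec)
        assert dem.values.min() >= -0.1 * 1200.0
        assert dem.values.max() <= 1.1 * 1200.0
        # gradient dominates: row means strictly increase
        row_means = dem.values.mean(axis=1)
        assert (np.diff(row_means) > 0).all()


class TestSpecies:
    def test_profiles_deterministic_under_seed(self):
        spec = ScenarioSpec(grid_rows=80, grid_cols=80, years=(2000, 2001),
                            habitat_fraction_initial=0.3, n_fragments_target=4, seed=5)
        p1, t1 = generate_species(spec, n_species=8)
        p2, t2 = generate_species(spec, n_species=8)
        assert [p.body_mass_g for p in p1] == [p.body_mass_g for p in p2]
        assert [p.species_id for p in p1] == [p.species_id for p in p2]
        assert {s: t.intended_category for s, t in t1.items()} == {
            s: t.intended_category for s, t in t2.items()
        }

    def test_ground_truth_areas_are_nonincreasing(self):
        spec = ScenarioSpec(grid_rows=80, grid_cols=80,
                            years=tuple(range(2000, 2010)),
                            habitat_fraction_initial=0.3, annual_loss_rate=0.03,
                            n_fragments_target=4, seed=5)
        _, truths = generate_species(spec, n_species=6)
        for t in truths.values():
            areas = [t.esh_km2_by_year[y] for y in sorted(t.esh_km2_by_year)]
            assert all(b <= a + 1e-9 for a, b in zip(areas, areas[1:]))


class TestCannedScenarios:
    def test_intended_categories_by_construction(self):
        named = {b.name: b for b in canned_scenarios(seed=0)}
        assert named["lc_stable"].truths["lc_stable"].intended_category == "LC"
        assert named["d1_cr"].truths["d1_cr"].intended_category == "CR"
        assert named["a2_cr"].truths["a2_cr"].intended_category == "CR"
        # d1_cr is engineered to 40 individuals against the default D1 thresholds
        t = named["d1_cr"].truths["d1_cr"]
        last = max(t.population_by_year)
        assert t.population_by_year[last] == pytest.approx(40.0)
        # a2_cr is engineered to an 85% loss over three generations
        t = named["a2_cr"].truths["a2_cr"]
        years = sorted(t.esh_km2_by_year)
        loss = 1 - t.esh_km2_by_year[years[-1]] / t.esh_km2_by_year[years[0]]
        assert loss == pytest.approx(0.85, abs=0.001)
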