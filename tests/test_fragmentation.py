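"""Fragment labeling, dispersal clumping, and severe-fragmentation verdicts."""

import numpy as np
import pytest

from autoredlist.errors import UnsupportedTaxonError
from autoredlist.fragmentation import (
    ClumpSet,
    SmallnessRule,
    clump,
    label_fragments,
    severe_fragmentation,
)
from autoredlist.demography import toy_viability_model
from helpers import clump_oracle, flood_fill_components, make_esh
from test_demography import mammal


def two_blocks(gap_cols=1, rows=6, cols=8):
    mask = np.zeros((rows, cols), dtype=bool)
    mask[1:3, 1:3] = True
    mask[1:3, 3 + gap_cols : 5 + gap_cols] = True
    return mask


class TestLabeling:
    def test_separated_blocks_are_two_fragments(self):
        esh = make_esh(two_blocks())
        assert label_fragments(esh, 2000).n_fragments == 2

    def test_diagonal_adjacency_semantics(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        esh = make_esh(mask)
        assert label_fragments(esh, 2000, "rook").n_fragments == 2
        assert label_fragments(esh, 2000, "queen").n_fragments == 1

    def test_empty_esh_has_no_fragments(self):
        esh = make_esh(np.zeros((5, 5), bool))
        assert label_fragments(esh, 2000).n_fragments == 0

    @pytest.mark.parametrize("adjacency", ["rook", "queen"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_flood_fill_oracle(self, adjacency, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((30, 30)) < 0.35
        esh = make_esh(mask)
        assert label_fragments(esh, 2000, adjacency).n_fragments == \
            flood_fill_components(mask, adjacency)

    def test_unknown_adjacency_rejected(self):
        with pytest.raises(ValueError):
            label_fragments(make_esh(np.ones((2, 2), bool)), 2000, "hex")


class TestClumping:
    def test_one_cell_gap_bridged_by_short_dispersal(self):
        # 300-m cells, one-cell gap: center distance 600 m, edge proxy 300 m
        esh = make_esh(two_blocks(), cell_size=300.0)
        frags = label_fragments(esh, 2000)
        assert clump(frags, 0.5).n_clumps == 1
        assert clump(frags, 0.2).n_clumps == 2

    def test_zero_dispersal_keeps_fragments_separate(self):
        frags = label_fragments(make_esh(two_blocks(), cell_size=300.0), 2000)
        assert clump(frags, 0.0).n_clumps == frags.n_fragments

    def test_chain_closure_is_transitive(self):
        # A–B close, B–C close, A–C far: all three in one clump
        mask = np.zeros((3, 12), dtype=bool)
        mask[1, 0] = mask[1, 3] = mask[1, 6] = True
        frags = label_fragments(make_esh(mask, cell_size=1000.0), 2000)
        # gaps: A-B and B-C are 2 km (proxy), A-C is 5 km
        clumps = clump(frags, 2.0)
        assert clumps.n_clumps == 1

    def test_clump_count_nonincreasing_in_dispersal(self, rng):
        mask = rng.random((25, 25)) < 0.2
        frags = label_fragments(make_esh(mask, cell_size=1000.0), 2000)
        counts = [clump(frags, d).n_clumps for d in np.linspace(0, 40, 10)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        if frags.n_fragments:
            assert clump(frags, 1e6).n_clumps == 1

    def test_partition_invariants(self, rng):
        mask = rng.random((20, 20)) < 0.3
        esh = make_esh(mask, cell_size=1000.0)
        frags = label_fragments(esh, 2000)
        clumps = clump(frags, 3.0)
        assert sorted(f for grp in clumps.members for f in grp) == frags.ids
        assert clumps.total_area_km2 == pytest.approx(sum(frags.areas().values()))
        assert clumps.total_area_km2 == pytest.approx(float(mask.sum()))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pairwise_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = rng.random((20, 20)) < 0.15
        frags = label_fragments(make_esh(mask, cell_size=1000.0), 2000)
        for d_km in (0.5, 2.0, 5.0):
            got = sorted((frozenset(m) for m in clump(frags, d_km).members), key=min)
            assert got == clump_oracle(frags.labels, 1000.0, d_km)


def clumpset(areas, pops=None, dispersal=1.0):
    return ClumpSet(
        members=[(i + 1,) for i in range(len(areas))],
        areas_km2=list(areas),
        populations=list(pops) if pops is not None else None,
        dispersal_km=dispersal,
    )


class TestSevereFragmentation:
    def test_single_clump_never_severe(self):
        for rule in (SmallnessRule("area_lt", 100.0), SmallnessRule("area_lt", 1e9)):
            v = severe_fragmentation(clumpset([10.0]), rule, 10.0)
            assert not v.severe

    def test_majority_small_area_triggers(self):
        # small clumps hold 6 of the 10 km² total
        v = severe_fragmentation(
            clumpset([3.0, 3.0, 4.0]), SmallnessRule("area_lt", 3.5), 10.0
        )
        assert v.severe and v.small_area_fraction == pytest.approx(0.6)

    def test_enumerated_clumps_against_rule(self):
        v = severe_fragmentation(
            clumpset([30.0, 30.0, 40.0]), SmallnessRule("area_lt", 35.0), 100.0
        )
        assert v.clump_verdicts == [True, True, False]
        assert v.small_area_fraction == pytest.approx(0.6)
        assert v.severe

    def test_individuals_rule_monotone_in_threshold(self):
        clumps = clumpset([20.0, 20.0, 60.0], pops=[50.0, 300.0, 5000.0])
        previous = False
        for thr in (10.0, 100.0, 500.0, 1000.0, 10000.0):
            v = severe_fragmentation(
                clumps, SmallnessRule("individuals_lt", thr), 100.0
            )
            assert previous <= v.severe  # raising the threshold never un-fragments
            previous = v.severe

    def test_population_rule_without_populations_rejected(self):
        with pytest.raises(ValueError, match="populations"):
            severe_fragmentation(
                clumpset([1.0, 2.0]), SmallnessRule("individuals_lt", 10.0), 3.0
            )

    def test_mvp_rule_for_birds_unsupported(self):
        bird = mammal(taxon="bird", key="default")
        with pytest.raises(UnsupportedTaxonError):
            severe_fragmentation(
                clumpset([1.0, 2.0], pops=[5.0, 5.0]),
                SmallnessRule("mvp", p=0.2),
                3.0,
                profile=bird,
                viability_model=toy_viability_model(),
            )

    def test_mvp_rule_uses_viability_threshold(self):
        p = mammal(key="rodent-like")  # MVP at p=0.2 is 2000 individuals
        clumps = clumpset([6.0, 4.0], pops=[1500.0, 2500.0])
        v = severe_fragmentation(
            clumps, SmallnessRule("mvp", p=0.2), 10.0,
            profile=p, viability_model=toy_viability_model(),
        )
        assert v.clump_verdicts == [True, False]
        assert v.severe

    def test_rule_parsing_roundtrip(self):
        assert SmallnessRule.parse("area_lt:100").rule_id == "area_lt:100"
        assert SmallnessRule.parse("mvp:0.4").p == 0.4
        with pytest.raises(ValueError):
            SmallnessRule.parse("bogus:1")
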