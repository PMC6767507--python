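"""Habitat fragments, dispersal clumps, and the severe-fragmentation test.

The Red List treats a range as severely fragmented when most individuals
live in small, relatively isolated subpopulations. Operationally:

1. contiguous suitable cells form **fragments** (connected components of
   the suitability raster under rook or queen adjacency);
2. fragments lying within the species' median dispersal distance of each
   other are merged into **clumps** — groups assumed to host
   demographically semi-isolated populations (isolation is thereby encoded
   by the clumping itself);
3. the range is **severely fragmented** iff clumps deemed *small* hold
   more than 50% of the total suitable area.

Because "small" has no quantitative IUCN definition, several alternative
rules are supported: a fixed area cutoff, a fixed number of individuals
(from the density model), or a minimum-viable-population target (mammals
only). Landscape barriers (rivers, roads) are deliberately ignored.

Fragment-to-fragment distance is approximated as the minimum distance
between suitable-cell centers minus one cell size, floored at zero — an
edge-to-edge proxy whose bias is below one cell diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .demography import ViabilityModel, mvp
from .errors import UnsupportedTaxonError
from .habitat import EshSeries, SpeciesProfile

ADJACENCY_STRUCTURES = {
    "rook": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    "queen": np.ones((3, 3), dtype=bool),
}


@dataclass
class FragmentSet:
    """Connected habitat fragments for one year."""

    labels: np.ndarray  # 0 = background, 1..n = fragment id
    cell_size: float  # metres
    cell_area_km2: float
    adjacency: str
    populations: Optional[dict[int, float]] = None

    @property
    def ids(self) -> list[int]:
        return list(range(1, int(self.labels.max()) + 1)) if self.labels.size else []

    @property
    def n_fragments(self) -> int:
        return int(self.labels.max())

    def cells(self, frag_id: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == frag_id)

    def area_km2(self, frag_id: int) -> float:
        return int((self.labels == frag_id).sum()) * self.cell_area_km2

    def areas(self) -> dict[int, float]:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_fragments + 1)
        return {i: counts[i] * self.cell_area_km2 for i in self.ids}


@dataclass
class ClumpSet:
    """Groups of fragments reachable within one dispersal distance."""

    members: list[tuple[int, ...]]  # fragment ids per clump
    areas_km2: list[float]
    populations: Optional[list[float]]
    dispersal_km: float

    @property
    def n_clumps(self) -> int:
        return len(self.members)

    @property
    def total_area_km2(self) -> float:
        return float(sum(self.areas_km2))


@dataclass
class SmallnessRule:
    """One quantitative definition of a *small* clump.

    kind ``area_lt``: area below ``threshold`` km² (the 100-km² rule);
    kind ``individuals_lt``: predicted population below ``threshold``;
    kind ``mvp``: population below the minimum-viable-population target at
    growth-rate proportion ``p`` (mammals only).
    """

    kind: str
    threshold: Optional[float] = None
    p: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("area_lt", "individuals_lt", "mvp"):
            raise ValueError(f"unknown smallness rule kind {self.kind!r}")
        if self.kind in ("area_lt", "individuals_lt"):
            if self.threshold is None or self.threshold <= 0:
                raise ValueError("rule threshold must be positive")
        if self.kind == "mvp" and self.p is None:
            raise ValueError("mvp rule requires a growth-rate proportion p")

    @property
    def rule_id(self) -> str:
        if self.kind == "mvp":
            return f"mvp:{self.p}"
        return f"{self.kind}:{self.threshold:g}"

    @classmethod
    def parse(cls, text: str) -> "SmallnessRule":
        kind, _, value = text.partition(":")
        if kind == "mvp":
            return cls(kind="mvp", p=float(value))
        return cls(kind=kind, threshold=float(value))


@dataclass
class FragmentationVerdict:
    severe: bool
    small_area_fraction: float
    clump_verdicts: list[bool]
    rule_id: str
    diagnostics: dict = field(default_factory=dict)


def label_fragments(esh: EshSeries, year: int, adjacency: str = "queen") -> FragmentSet:
    """Connected components of the suitable-cell graph for one year."""
    if adjacency not in ADJACENCY_STRUCTURES:
        raise ValueError(f"adjacency must be rook or queen, got {adjacency!r}")
    mask = esh.mask(year)
    labels, _ = ndimage.label(mask, structure=ADJACENCY_STRUCTURES[adjacency])
    return FragmentSet(
        labels=labels,
        cell_size=esh.grid.cell_size,
        cell_area_km2=esh.grid.cell_area_km2,
        adjacency=adjacency,
    )


def _pairwise_gaps_m(frags: FragmentSet) -> np.ndarray:
    """Edge-to-edge gap proxy (metres) between every fragment pair."""
    ids = frags.ids
    n = len(ids)
    gaps = np.zeros((n, n))
    points = {}
    trees = {}
    for i, fid in enumerate(ids):
        rr, cc = frags.cells(fid)
        pts = np.column_stack([cc * frags.cell_size, rr * frags.cell_size])
        points[i] = pts
        trees[i] = cKDTree(pts)
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = trees[j].query(points[i], k=1)
            gap = max(0.0, float(d.min()) - frags.cell_size)
            gaps[i, j] = gaps[j, i] = gap
    return gaps


def clump(frags: FragmentSet, dispersal_km: float) -> ClumpSet:
    """Merge fragments into clumps by transitive dispersal reachability.

    Two fragments are linked when their edge-to-edge gap is at most the
    median dispersal distance; clumps are the connected components of that
    relation, so a chain of pairwise-reachable fragments forms one clump.
    """
    if dispersal_km < 0:
        raise ValueError("dispersal distance must be non-negative")
    ids = frags.ids
    if not ids:
        return ClumpSet(members=[], areas_km2=[], populations=None, dispersal_km=dispersal_km)
    n = len(ids)
    gaps = _pairwise_gaps_m(frags)
    link = gaps <= dispersal_km * 1000.0
    np.fill_diagonal(link, True)
    ii, jj = np.nonzero(link)
    graph = coo_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)

    areas = frags.areas()
    members: list[list[int]] = [[] for _ in range(n_comp)]
    for idx, fid in enumerate(ids):
        members[comp[idx]].append(fid)
    clump_areas = [sum(areas[f] for f in grp) for grp in members]
    pops = None
    if frags.populations is not None:
        pops = [sum(frags.populations[f] for f in grp) for grp in members]
    return ClumpSet(
        members=[tuple(sorted(g)) for g in members],
        areas_km2=clump_areas,
        populations=pops,
        dispersal_km=dispersal_km,
    )


def severe_fragmentation(
    clumps: ClumpSet,
    rule: SmallnessRule,
    total_esh_area_km2: float,
    profile: Optional[SpeciesProfile] = None,
    viability_model: Optional[ViabilityModel] = None,
) -> FragmentationVerdict:
    """Decide severe fragmentation: >50% of ESH in small clumps.

    For population-based rules the clump populations must have been
    attached (``FragmentSet.populations`` before clumping). The MVP rule is
    defined for mammals only and needs a profile plus viability model.
    """
    if rule.kind == "mvp":
        if profile is None or viability_model is None:
            raise ValueError("mvp rule requires a species profile and viability model")
        if profile.taxon_class != "mammal":
            raise UnsupportedTaxonError(
                "MVP-based smallness is defined for mammals only"
            )
        threshold = mvp(viability_model, profile, rule.p)
    else:
        threshold = rule.threshold

    verdicts: list[bool] = []
    small_area = 0.0
    for k in range(clumps.n_clumps):
        if rule.kind == "area_lt":
            small = clumps.areas_km2[k] < threshold
        else:
            if clumps.populations is None:
                raise ValueError(f"rule {rule.rule_id} needs clump populations")
            small = clumps.populations[k] < threshold
        verdicts.append(small)
        if small:
            small_area += clumps.areas_km2[k]

    fraction = small_area / total_esh_area_km2 if total_esh_area_km2 > 0 else 0.0
    # a single clump holds the entire (semi-connected) population: smallness
    # without isolation is not fragmentation
    return FragmentationVerdict(
        severe=fraction > 0.5 and clumps.n_clumps > 1,
        small_area_fraction=fraction,
        clump_verdicts=verdicts,
        rule_id=rule.rule_id,
        diagnostics={
            "threshold": threshold,
            "n_clumps": clumps.n_clumps,
            "dispersal_km": clumps.dispersal_km,
        },
    )
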