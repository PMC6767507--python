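"""Synthetic landscapes, species, and ground truth.

Every downstream stage of the assessment pipeline (habitat extraction,
demography, fragmentation, the criteria engine, agreement statistics) is
testable without external downloads: this module fabricates an annual
categorical land-cover series with a controlled habitat-loss rate and
fragment geometry, a smooth elevation surface, species range polygons
tied to known fragments, and trait tables — together with the ground
truth (habitat area per year, population, intended category) implied by
the construction.

Landscape model
---------------
Habitat starts as ``n_fragments_target`` rectangular blocks spread evenly
over the grid (or as randomly scattered cells in ``scatter`` layout) so
the initial habitat fraction is hit exactly. Each subsequent year removes
cells to track ``initial · (1 − annual_loss_rate)^(year − year₀)``. The
default removal order erodes fragment edges inward (cells closest to the
habitat boundary go first), which keeps fragment geometry interpretable;
a ``random`` dropout mode removes uniformly chosen habitat cells instead.
All randomness flows from the single scenario seed.

Elevation is a linear gradient plus a low-frequency sinusoidal ripple, so
altitude masking produces contiguous bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .demography import (
    DensityModel,
    DispersalModel,
    ViabilityModel,
    constant_density_model,
    predict_density,
    toy_density_model,
    toy_dispersal_model,
    toy_viability_model,
)
from .grids import GridSpec, Raster
from .habitat import Crosswalk, LandCoverSeries, SpeciesProfile


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic landscape scenario."""

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 1000.0  # metres
    years: tuple[int, ...] = tuple(range(1992, 2016))
    legend: tuple[int, ...] = (1, 2)  # legend[0] is the habitat-forming code
    habitat_fraction_initial: float = 0.5
    annual_loss_rate: float = 0.0
    n_fragments_target: int = 4
    gap_width: float = 2000.0  # metres, minimum separation between fragments
    elevation_range: float = 1000.0  # metres
    seed: int = 0
    loss_mode: str = "erode"  # or "random"
    layout: str = "blocks"  # or "scatter"

    def validate(self) -> None:
        if not self.legend:
            raise ValueError("legend must not be empty")
        if len(self.legend) < 2:
            raise ValueError("legend needs a habitat code and a matrix code")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if not 0.0 <= self.habitat_fraction_initial <= 1.0:
            raise ValueError("habitat_fraction_initial must lie in [0, 1]")
        if not 0.0 <= self.annual_loss_rate <= 1.0:
            raise ValueError("annual_loss_rate must lie in [0, 1]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_fragments_target < 1:
            raise ValueError("n_fragments_target must be at least 1")
        if self.loss_mode not in ("erode", "random"):
            raise ValueError("loss_mode must be erode or random")
        if self.layout not in ("blocks", "scatter"):
            raise ValueError("layout must be blocks or scatter")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(rows=self.grid_rows, cols=self.grid_cols, cell_size=self.cell_size)

    @property
    def habitat_code(self) -> int:
        return self.legend[0]

    @property
    def matrix_code(self) -> int:
        return self.legend[1]


#: habitat-scheme codes used by synthetic crosswalks (level-2 style strings)
_SCHEME_CODES = ("1.6", "14.1", "4.4", "3.5", "8.1")


def default_crosswalk(legend: tuple[int, ...] = (1, 2)) -> Crosswalk:
    """Crosswalk mapping each synthetic legend code to one habitat code."""
    mapping = {
        code: frozenset({_SCHEME_CODES[i % len(_SCHEME_CODES)]})
        for i, code in enumerate(legend)
    }
    return Crosswalk(mapping)


@dataclass
class GroundTruth:
    """Construction-time truth for one synthetic species."""

    species_id: str
    esh_km2_by_year: dict[int, float]
    population_by_year: Optional[dict[int, float]] = None
    fragment_count: Optional[int] = None
    intended_category: Optional[str] = None


@dataclass
class ScenarioBundle:
    """A complete self-contained scenario: rasters, species, truth, models."""

    name: str
    spec: ScenarioSpec
    landcover: LandCoverSeries
    dem: Raster
    crosswalk: Crosswalk
    profiles: list[SpeciesProfile]
    truths: dict[str, GroundTruth]
    density_model: DensityModel
    dispersal_model: DispersalModel
    viability_model: ViabilityModel


# ---------------------------------------------------------------------------
# Landscape generation


def _block_layout(spec: ScenarioSpec, total: int) -> tuple[np.ndarray, list[dict]]:
    rows, cols = spec.grid_rows, spec.grid_cols
    n = min(spec.n_fragments_target, total) if total else 0
    mask = np.zeros((rows, cols), dtype=bool)
    frags: list[dict] = []
    if total == 0:
        return mask, frags
    if total == rows * cols:
        mask[:] = True
        return mask, [{"r0": 0, "c0": 0, "side": max(rows, cols), "count": total}]

    gap_cells = max(1, math.ceil(spec.gap_width / spec.cell_size))
    base, rem = divmod(total, n)
    counts = [base + (1 if i < rem else 0) for i in range(n)]
    side = math.ceil(math.sqrt(max(counts)))
    k_cols = math.ceil(math.sqrt(n))
    k_rows = math.ceil(n / k_cols)
    pitch_r = rows // k_rows
    pitch_c = cols // k_cols
    if side > pitch_r - gap_cells or side > pitch_c - gap_cells:
        raise ValueError(
            f"grid too small for {n} fragments of side {side} with gap "
            f"{gap_cells} cells"
        )
    for f, count in enumerate(counts):
        i, j = divmod(f, k_cols)
        r0 = i * pitch_r + (pitch_r - side) // 2
        c0 = j * pitch_c + (pitch_c - side) // 2
        full_rows, tail = divmod(count, side)
        mask[r0 : r0 + full_rows, c0 : c0 + side] = True
        if tail:
            mask[r0 + full_rows, c0 : c0 + tail] = True
        frags.append({"r0": r0, "c0": c0, "side": side, "count": count})
    return mask, frags


def _initial_mask(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[np.ndarray, list[dict]]:
    total = round(spec.habitat_fraction_initial * spec.grid_rows * spec.grid_cols)
    if spec.layout == "scatter":
        mask = np.zeros(spec.grid_rows * spec.grid_cols, dtype=bool)
        if total:
            idx = rng.choice(mask.size, size=total, replace=False)
            mask[idx] = True
        return mask.reshape(spec.grid_rows, spec.grid_cols), []
    return _block_layout(spec, total)


def _remove_cells(mask: np.ndarray, n_remove: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Remove exactly ``n_remove`` habitat cells, eroding edges or at random."""
    if n_remove <= 0:
        return mask
    out = mask.copy()
    if mode == "random":
        idx = np.flatnonzero(out)
        drop = rng.choice(idx, size=n_remove, replace=False)
        out.flat[drop] = False
        return out
    # edge erosion: peel cells nearest the habitat boundary first; the raster
    # border counts as boundary so full-grid habitat erodes from the edges in
    padded = np.pad(out, 1)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    flat = np.flatnonzero(out)
    order = flat[np.lexsort((flat, edt.flat[flat]))]
    out.flat[order[:n_remove]] = False
    return out


def generate_landcover(spec: ScenarioSpec) -> LandCoverSeries:
    """Generate the annual categorical land-cover stack for a scenario.

    Year *t* holds ``round(initial · (1 − loss)^(t − t₀))`` habitat cells;
    if the loss rate exhausts the habitat before the final year, later
    years are emitted with zero habitat and ``meta["exhausted"]`` is set.
    Output is bit-identical for a fixed spec (the seed drives all
    randomness).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask, frags = _initial_mask(spec, rng)
    initial_total = int(mask.sum())

    n_years = len(spec.years)
    data = np.full((n_years, spec.grid_rows, spec.grid_cols), spec.matrix_code, dtype=np.int16)
    exhausted = False
    current = mask
    for i, year in enumerate(spec.years):
        target = round(initial_total * (1.0 - spec.annual_loss_rate) ** (year - spec.years[0]))
        target = max(0, target)
        current = _remove_cells(current, int(current.sum()) - target, spec.loss_mode, rng)
        if target == 0 and initial_total > 0:
            exhausted = True
        data[i][current] = spec.habitat_code

    return LandCoverSeries(
        grid=spec.grid,
        years=spec.years,
        data=data,
        legend=frozenset(spec.legend),
        meta={
            "fragments": frags,
            "initial_habitat_cells": initial_total,
            "exhausted": exhausted,
            "layout": spec.layout,
            "loss_mode": spec.loss_mode,
            "seed": spec.seed,
        },
    )


def generate_elevation(spec: ScenarioSpec) -> Raster:
    """Smooth synthetic elevation: linear gradient plus low-frequency ripple."""
    rng = np.random.default_rng(spec.seed + 17)
    phase_r, phase_c = rng.uniform(0, 2 * math.pi, size=2)
    rr, cc = np.meshgrid(
        np.arange(spec.grid_rows), np.arange(spec.grid_cols), indexing="ij"
    )
    base = spec.elevation_range * rr / max(1, spec.grid_rows - 1)
    ripple = 0.05 * spec.elevation_range * (
        np.sin(2 * math.pi * rr / spec.grid_rows + phase_r)
        * np.sin(2 * math.pi * cc / spec.grid_cols + phase_c)
    )
    return Raster(grid=spec.grid, values=base + ripple)


# ---------------------------------------------------------------------------
# Species generation

DEFAULT_TRAIT_RANGES = {
    "body_mass_g": (50.0, 50000.0),  # sampled log-uniformly
    "generation_length_yr": (2.0, 12.0),
}

_DIETS = ("carnivore", "herbivore", "omnivore")


def _fragment_box(frag: dict, spec: ScenarioSpec):
    """Bounding box of a block fragment in projected metres, half-cell buffered."""
    cs = spec.cell_size
    rows = spec.grid_rows
    r0, c0, side = frag["r0"], frag["c0"], frag["side"]
    n_rows = math.ceil(frag["count"] / side)
    x0 = c0 * cs
    x1 = (c0 + side) * cs
    y1 = (rows - r0) * cs
    y0 = (rows - r0 - n_rows) * cs
    return box(x0 - cs, y0 - cs, x1 + cs, y1 + cs)


def generate_species(
    spec: ScenarioSpec,
    trait_ranges: Optional[dict] = None,
    n_species: int = 10,
    bat_fraction: float = 0.15,
    unsuitable_fraction: float = 0.06,
    density_model: Optional[DensityModel] = None,
) -> tuple[list[SpeciesProfile], dict[str, GroundTruth]]:
    """Random species tied to the scenario's fragments, with ground truth.

    Each species' range is the convex hull of a random subset of fragment
    bounding boxes; traits are drawn from ``trait_ranges``. A small share
    of species gets habitat codes absent from the landscape (their ESH is
    empty by construction, exercising the exclusion rule). Ground truth —
    true habitat area per year, population, and the category the default
    engine thresholds imply — is computed from the construction itself.
    Deterministic for a fixed scenario seed.
    """
    spec.validate()
    ranges = dict(DEFAULT_TRAIT_RANGES)
    if trait_ranges:
        ranges.update(trait_ranges)
    lc = generate_landcover(spec)
    dem = generate_elevation(spec)
    xwalk = default_crosswalk(spec.legend)
    frags = lc.meta["fragments"]
    if not frags:
        raise ValueError("generate_species requires a blocks-layout scenario")
    density_model = density_model or toy_density_model()

    rng = np.random.default_rng(spec.seed + 1000)
    habitat_scheme_code = next(iter(xwalk.mapping[spec.habitat_code]))
    profiles: list[SpeciesProfile] = []
    truths: dict[str, GroundTruth] = {}

    from .pipeline import AssessmentOptions, compute_metrics  # local to avoid cycle
    from .engine import assess

    for s in range(n_species):
        sid = f"sp{s:03d}"
        k = int(rng.integers(1, min(6, len(frags)) + 1))
        chosen = rng.choice(len(frags), size=k, replace=False)
        geom = unary_union(
            [_fragment_box(frags[i], spec) for i in sorted(chosen)]
        ).convex_hull
        taxon = "bird" if rng.random() < 0.5 else "mammal"
        is_bat = taxon == "mammal" and rng.random() < bat_fraction
        lo, hi = ranges["body_mass_g"]
        mass = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        glo, ghi = ranges["generation_length_yr"]
        gl = float(rng.uniform(glo, ghi))
        codes = frozenset({habitat_scheme_code})
        if rng.random() < unsuitable_fraction:
            codes = frozenset({"17.1"})  # maps to nothing on this landscape
        alt_min = alt_max = None
        if rng.random() < 0.2:
            alt_min = 0.0
            alt_max = float(rng.uniform(0.5, 1.0) * spec.elevation_range)
        profile = SpeciesProfile(
            species_id=sid,
            taxon_class=taxon,
            is_bat=is_bat,
            suitable_habitat_codes=codes,
            body_mass_g=mass,
            generation_length_yr=gl,
            diet=str(rng.choice(_DIETS)),
            order_tag="default",
            density_key="default",
            altitude_min_m=alt_min,
            altitude_max_m=alt_max,
            season_polygons={"resident": geom},
        )
        profiles.append(profile)

        metrics = compute_metrics(
            profile, lc, xwalk, dem,
            density_model=density_model,
            dispersal_model=toy_dispersal_model(),
            viability_model=toy_viability_model(),
            options=AssessmentOptions(),
        )
        if metrics.zero_esh:
            intended = None
        else:
            intended = assess(metrics, mode="decline_only").final_category
        esh_by_year = metrics.extras.get("esh_km2_by_year", {})
        pop_by_year = metrics.extras.get("population_by_year")
        truths[sid] = GroundTruth(
            species_id=sid,
            esh_km2_by_year=esh_by_year,
            population_by_year=pop_by_year,
            fragment_count=None,
            intended_category=intended,
        )

    return profiles, truths


def _noisy_published(
    intended: Optional[str],
    rng: np.random.Generator,
    shift_prob: float = 0.15,
    dd_prob: float = 0.06,
) -> Optional[str]:
    """Emulate published-assessment disagreement around the intended category."""
    if intended is None:
        return None
    if rng.random() < dd_prob:
        return "DD"
    order = ["LC", "VU", "EN", "CR"]
    idx = order.index(intended)
    u = rng.random()
    if u < shift_prob:
        idx = min(3, idx + 1)
    elif u < 2 * shift_prob:
        idx = max(0, idx - 1)
    if idx == 0 and rng.random() < 0.3:
        return "NT"
    return order[idx]


def generate_batch(
    n_species: int = 50,
    seed: int = 0,
    spec: Optional[ScenarioSpec] = None,
) -> ScenarioBundle:
    """A multi-species scenario with noisy published categories attached.

    The default landscape is a 200×200 km grid of sixteen habitat blocks
    losing 1% of habitat per year over 1996–2015 — enough structure for
    every criterion and both fragmentation modes to engage.
    """
    spec = spec or ScenarioSpec(
        grid_rows=200,
        grid_cols=200,
        cell_size=1000.0,
        years=tuple(range(1996, 2016)),
        habitat_fraction_initial=0.25,
        annual_loss_rate=0.01,
        n_fragments_target=16,
        gap_width=2000.0,
        seed=seed,
    )
    spec = replace(spec, seed=seed)
    lc = generate_landcover(spec)
    dem = generate_elevation(spec)
    xwalk = default_crosswalk(spec.legend)
    profiles, truths = generate_species(spec, n_species=n_species)
    rng = np.random.default_rng(spec.seed + 2000)
    for p in profiles:
        p.published_category = _noisy_published(truths[p.species_id].intended_category, rng)
    return ScenarioBundle(
        name="batch",
        spec=spec,
        landcover=lc,
        dem=dem,
        crosswalk=xwalk,
        profiles=profiles,
        truths=truths,
        density_model=toy_density_model(),
        dispersal_model=toy_dispersal_model(),
        viability_model=toy_viability_model(),
    )


# ---------------------------------------------------------------------------
# Canned scenarios — one species each, engineered so a specific criterion
# drives the intended category.


def _single_species_bundle(
    name: str,
    spec: ScenarioSpec,
    density: float,
    generation_length_yr: float,
    intended: str,
    taxon: str = "mammal",
) -> ScenarioBundle:
    lc = generate_landcover(spec)
    dem = generate_elevation(spec)
    xwalk = default_crosswalk(spec.legend)
    geom = box(0, 0, spec.grid_cols * spec.cell_size, spec.grid_rows * spec.cell_size)
    habitat_scheme_code = next(iter(xwalk.mapping[spec.habitat_code]))
    profile = SpeciesProfile(
        species_id=name,
        taxon_class=taxon,
        suitable_habitat_codes=frozenset({habitat_scheme_code}),
        body_mass_g=1000.0,
        generation_length_yr=generation_length_yr,
        diet="omnivore",
        order_tag="default",
        density_key="default",
        season_polygons={"resident": geom},
    )
    cell_area = spec.grid.cell_area_km2
    esh_by_year = {}
    for i, year in enumerate(spec.years):
        esh_by_year[year] = int((lc.data[i] == spec.habitat_code).sum()) * cell_area
    truth = GroundTruth(
        species_id=name,
        esh_km2_by_year=esh_by_year,
        population_by_year={y: density * a for y, a in esh_by_year.items()},
        fragment_count=spec.n_fragments_target if spec.layout == "blocks" else None,
        intended_category=intended,
    )
    return ScenarioBundle(
        name=name,
        spec=spec,
        landcover=lc,
        dem=dem,
        crosswalk=xwalk,
        profiles=[profile],
        truths={name: truth},
        density_model=constant_density_model(density),
        dispersal_model=toy_dispersal_model(),
        viability_model=toy_viability_model(),
    )


def canned_scenarios(seed: int = 0) -> list[ScenarioBundle]:
    """Engineered single-species scenarios, one per target criterion.

    * ``lc_stable``  — huge stable range: everything LC.
    * ``a2_cr``      — 85% habitat (and population) loss within 3
      generations: CR under A2.
    * ``d1_cr``      — a stable population of 40 individuals: CR under D1.
    * ``b2_en``      — AOO ≈ 220 km² with continuing habitat decline:
      EN under B2.
    * ``c1_vu``      — ~8,400 individuals declining 12% over the
      10-year window: VU under C1.
    """
    years = tuple(range(1992, 2016))
    bundles = []

    bundles.append(
        _single_species_bundle(
            "lc_stable",
            ScenarioSpec(
                grid_rows=160, grid_cols=160, years=years, seed=seed,
                habitat_fraction_initial=0.5, annual_loss_rate=0.0,
                n_fragments_target=1,
            ),
            density=10.0, generation_length_yr=5.0, intended="LC",
        )
    )
    bundles.append(
        _single_species_bundle(
            "a2_cr",
            ScenarioSpec(
                grid_rows=160, grid_cols=160, years=years, seed=seed,
                habitat_fraction_initial=0.5,
                # 85% total loss over the 23 calendar-year span
                annual_loss_rate=1.0 - 0.15 ** (1.0 / 23.0),
                n_fragments_target=4,
            ),
            density=10.0, generation_length_yr=8.0, intended="CR",
        )
    )
    bundles.append(
        _single_species_bundle(
            "d1_cr",
            ScenarioSpec(
                grid_rows=60, grid_cols=60, years=years, seed=seed,
                habitat_fraction_initial=20.0 / 3600.0, annual_loss_rate=0.0,
                n_fragments_target=1,
            ),
            density=2.0, generation_length_yr=4.0, intended="CR",
        )
    )
    bundles.append(
        _single_species_bundle(
            "b2_en",
            ScenarioSpec(
                grid_rows=160, grid_cols=160, years=years, seed=seed,
                habitat_fraction_initial=200.0 / 25600.0, annual_loss_rate=0.003,
                n_fragments_target=1,
            ),
            density=60.0, generation_length_yr=2.0, intended="EN",
        )
    )
    bundles.append(
        _single_species_bundle(
            "c1_vu",
            ScenarioSpec(
                grid_rows=160, grid_cols=160, years=years, seed=seed,
                habitat_fraction_initial=1024.0 / 25600.0,
                # 12% loss over the trailing 10-year window
                annual_loss_rate=1.0 - 0.88 ** (1.0 / 10.0),
                layout="scatter", loss_mode="random",
            ),
            density=11.0, generation_length_yr=2.0, intended="VU",
        )
    )
    return bundles
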