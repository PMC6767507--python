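"""Range geometry, suitable-habitat extraction, and trend windows.

This module turns a species' range polygons, habitat preferences, and
altitude limits plus an annual land-cover time series into the quantities
the Red List criteria consume:

* **EOO** (extent of occurrence): area of the minimum convex polygon
  around the range. For migratory species mapped with separate breeding
  and non-breeding ranges, the EOO is the smaller of the two hulls built
  from (resident + breeding) and (resident + non-breeding).
* **ESH** (extent of suitable habitat): the cells inside the range whose
  land-cover class crosswalks to one of the species' suitable habitat
  codes and whose elevation lies within the species' altitude limits,
  evaluated per year.
* **AOO** (area of occupancy): an upper-bound estimate obtained by
  upscaling the ESH to a 2-km reference grid — any coarse cell containing
  at least one suitable fine-cell center counts in full.
* **Trend windows**: criterion time windows of the form
  max(floor_years, n × generation length) ending at the last mapped year,
  with a linear rescaling of the observed change when the window exceeds
  the mapped span.

Cell membership is decided by the cell-center point: a cell belongs to a
polygon iff its center does, and a fine cell belongs to the coarse cell
containing its center (the coarse grid is anchored at the fine-grid
origin). This keeps fine→polygon and fine→coarse assignment symmetric and
well-defined even when the coarse cell size is not an integer multiple of
the fine one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import GridMismatchError, UnknownCodeError
from .grids import GridSpec, Raster

SEASONS = ("resident", "breeding", "nonbreeding")

#: sentinel for a trend that cannot be computed (zero baseline)
UNDEFINED_TREND = float("nan")


@dataclass
class LandCoverSeries:
    """Annual categorical land-cover rasters on one shared grid."""

    grid: GridSpec
    years: tuple[int, ...]
    data: np.ndarray  # shape (n_years, rows, cols), integer codes
    legend: frozenset[int]
    nodata: int = -9999
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if self.data.shape != (len(self.years), self.grid.rows, self.grid.cols):
            raise ValueError("data shape does not match (years, rows, cols)")

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} not in series {self.years[0]}–{self.years[-1]}")


@dataclass
class Crosswalk:
    """Mapping from land-cover legend codes to habitat-scheme codes.

    Every legend code must be present; a code may map to the empty set
    (land cover that matches no habitat class, e.g. open water for a
    terrestrial scheme).
    """

    mapping: dict[int, frozenset[str]]

    def __post_init__(self):
        self.mapping = {int(k): frozenset(v) for k, v in self.mapping.items()}

    def validate_legend(self, legend) -> None:
        missing = set(legend) - set(self.mapping)
        if missing:
            raise UnknownCodeError(missing)

    def suitable_lc_codes(self, habitat_codes: frozenset[str]) -> frozenset[int]:
        """Land-cover codes whose habitat classes intersect the species' codes."""
        return frozenset(c for c, habs in self.mapping.items() if habs & habitat_codes)

    @classmethod
    def from_csv(cls, path) -> "Crosswalk":
        import pandas as pd

        df = pd.read_csv(path, dtype={"habitat_code": str})
        mapping: dict[int, set[str]] = {}
        for code, hab in zip(df["lc_code"], df["habitat_code"]):
            mapping.setdefault(int(code), set())
            if isinstance(hab, str) and hab and hab.lower() != "none":
                mapping[int(code)].add(hab)
        return cls({k: frozenset(v) for k, v in mapping.items()})

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for code in sorted(self.mapping):
            habs = sorted(self.mapping[code])
            if not habs:
                rows.append({"lc_code": code, "habitat_code": "none"})
            for h in habs:
                rows.append({"lc_code": code, "habitat_code": h})
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class SpeciesProfile:
    """Per-species attributes needed for an assessment."""

    species_id: str
    taxon_class: str  # "bird" | "mammal"
    suitable_habitat_codes: frozenset[str]
    body_mass_g: float
    generation_length_yr: float
    diet: str = "omnivore"
    order_tag: str = ""
    is_bat: bool = False
    altitude_min_m: Optional[float] = None
    altitude_max_m: Optional[float] = None
    season_polygons: dict[str, Optional[BaseGeometry]] = field(default_factory=dict)
    published_category: Optional[str] = None  # LC/NT/VU/EN/CR/DD
    density_key: Optional[str] = None
    threat_flag: Optional[bool] = None  # D2 "plausible threats" override

    def __post_init__(self):
        if self.taxon_class not in ("bird", "mammal"):
            raise ValueError(f"taxon_class must be bird or mammal, got {self.taxon_class!r}")
        if self.generation_length_yr <= 0:
            raise ValueError("generation_length_yr must be positive")
        if (
            self.altitude_min_m is not None
            and self.altitude_max_m is not None
            and self.altitude_min_m > self.altitude_max_m
        ):
            raise ValueError("altitude_min_m exceeds altitude_max_m")
        self.suitable_habitat_codes = frozenset(self.suitable_habitat_codes)
        if not any(g is not None for g in self.season_polygons.values()):
            raise ValueError("at least one season polygon is required")

    def season(self, name: str) -> Optional[BaseGeometry]:
        return self.season_polygons.get(name)

    @property
    def is_migratory(self) -> bool:
        return self.season("breeding") is not None and self.season("nonbreeding") is not None

    def range_union(self) -> BaseGeometry:
        geoms = [g for g in self.season_polygons.values() if g is not None]
        return unary_union(geoms)


@dataclass
class EshSeries:
    """Per-year binary suitability masks within a species' range."""

    grid: GridSpec
    years: tuple[int, ...]
    masks: np.ndarray  # (n_years, rows, cols) bool
    range_mask: np.ndarray  # (rows, cols) bool
    empty_flag: bool = False

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} not in ESH series")

    def mask(self, year: int) -> np.ndarray:
        return self.masks[self.year_index(year)]

    def area_series(self) -> dict[int, float]:
        return {y: esh_area(self, y) for y in self.years}


# ---------------------------------------------------------------------------
# EOO


def _hull_area_km2(geoms) -> float:
    geoms = [g for g in geoms if g is not None and not g.is_empty]
    if not geoms:
        return 0.0
    hull = unary_union(geoms).convex_hull
    return hull.area / 1e6


def compute_eoo(profile: SpeciesProfile) -> float:
    """Extent of occurrence (km²) as a minimum convex polygon.

    Non-migratory: convex hull over all season polygons. Migratory (both
    breeding and non-breeding present): the smaller of hull(resident ∪
    breeding) and hull(resident ∪ nonbreeding). Degenerate ranges
    (point/line) give EOO 0 with a warning.
    """
    if profile.is_migratory:
        res = profile.season("resident")
        area = min(
            _hull_area_km2([res, profile.season("breeding")]),
            _hull_area_km2([res, profile.season("nonbreeding")]),
        )
    else:
        area = _hull_area_km2(profile.season_polygons.values())
    if area == 0.0:
        warnings.warn(
            f"{profile.species_id}: degenerate range geometry, EOO set to 0",
            stacklevel=2,
        )
    return area


# ---------------------------------------------------------------------------
# ESH


def rasterize_mask(geom: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside ``geom``."""
    xs, ys = grid.cell_centers()
    X, Y = np.meshgrid(xs, ys)
    shapely.prepare(geom)
    return shapely.contains_xy(geom, X, Y)


def build_esh(
    profile: SpeciesProfile,
    lc: LandCoverSeries,
    xwalk: Crosswalk,
    dem: Optional[Raster] = None,
) -> EshSeries:
    """Per-year suitable-habitat masks for one species.

    A cell is suitable in year *t* iff its center lies inside the range,
    its land-cover code crosswalks to at least one of the species' suitable
    habitat codes, and (when altitude limits are set) its elevation lies in
    [altitude_min, altitude_max]. Species whose preferences yield no
    suitable habitat in any year get ``empty_flag=True`` so the caller can
    exclude them explicitly rather than silently.
    """
    if dem is not None:
        lc.grid.require_match(dem.grid, "elevation")
    present = set(np.unique(lc.data).tolist()) - {lc.nodata}
    unknown = present - set(xwalk.mapping)
    if unknown:
        raise UnknownCodeError(unknown)

    suitable_codes = xwalk.suitable_lc_codes(profile.suitable_habitat_codes)
    range_mask = rasterize_mask(profile.range_union(), lc.grid)

    alt_mask = np.ones_like(range_mask, dtype=bool)
    if dem is not None:
        elev = dem.values
        if profile.altitude_min_m is not None:
            alt_mask &= elev >= profile.altitude_min_m
        if profile.altitude_max_m is not None:
            alt_mask &= elev <= profile.altitude_max_m

    base = range_mask & alt_mask
    code_list = sorted(suitable_codes)
    masks = np.zeros_like(lc.data, dtype=bool)
    for i in range(len(lc.years)):
        masks[i] = base & np.isin(lc.data[i], code_list)

    return EshSeries(
        grid=lc.grid,
        years=lc.years,
        masks=masks,
        range_mask=range_mask,
        empty_flag=not masks.any(),
    )


def esh_area(esh: EshSeries, year: int) -> float:
    """Suitable-habitat area (km²) in ``year``: cell count × cell area."""
    return int(esh.mask(year).sum()) * esh.grid.cell_area_km2


def upscale_aoo(esh: EshSeries, year: int, coarse_cell_size: float = 2000.0) -> float:
    """Area of occupancy (km²) on a coarse reference grid.

    Any coarse cell containing the center of at least one suitable fine
    cell contributes its full area; this mirrors the standard procedure of
    harmonizing occupancy estimates to a 2×2 km grid and gives an upper
    bound on true occupancy. The coarse grid is anchored at the fine-grid
    origin.
    """
    if coarse_cell_size < esh.grid.cell_size:
        raise ValueError("coarse cell must not be smaller than the fine cell")
    rr, cc = np.nonzero(esh.mask(year))
    if rr.size == 0:
        return 0.0
    g = esh.grid
    fx = (cc + 0.5) * g.cell_size  # offsets from the fine-grid origin
    fy = (g.rows - rr - 0.5) * g.cell_size
    ci = np.floor(fx / coarse_cell_size).astype(np.int64)
    cj = np.floor(fy / coarse_cell_size).astype(np.int64)
    n_coarse = np.unique(ci * (2**32) + cj).size
    return n_coarse * (coarse_cell_size / 1000.0) ** 2


# ---------------------------------------------------------------------------
# Trend windows


def criterion_window(
    floor_years: float,
    n_generations: float,
    generation_length_yr: float,
    first_year: int,
    last_year: int,
) -> tuple[int, float]:
    """Start year and scale factor for a criterion time window.

    The window is max(floor_years, n_generations × GL) years ending at
    ``last_year``. The mapped series spans ``last_year − first_year + 1``
    years (an annual series 1992–2015 covers 24 years). If the window fits,
    the change is measured over the trailing sub-window unscaled; if it is
    longer than the mapped span, the change over the full span is linearly
    rescaled by window/span.
    """
    if generation_length_yr <= 0:
        raise ValueError("generation length must be positive")
    if last_year <= first_year:
        raise ValueError("last_year must exceed first_year")
    window = max(float(floor_years), n_generations * generation_length_yr)
    span = last_year - first_year + 1
    if window <= span:
        start = max(first_year, last_year - int(round(window)))
        return start, 1.0
    return first_year, window / span


def trend_window(
    generation_length_yr: float, first_year: int, last_year: int
) -> tuple[int, float]:
    """Window for population reduction: max(10 years, 3 generations)."""
    return criterion_window(10.0, 3.0, generation_length_yr, first_year, last_year)


def percent_change(
    series: Mapping[int, float],
    start_year: int,
    end_year: int,
    scale_factor: float = 1.0,
) -> float:
    """Scaled percent change of a yearly series between two mapped years.

    Returns 100·(v_end − v_start)/v_start·scale_factor. A zero baseline
    makes the trend undefined: NaN is returned and callers must treat the
    dependent criteria as not evaluated.
    """
    if start_year not in series or end_year not in series:
        raise KeyError(f"years {start_year}/{end_year} not both present in series")
    v0 = series[start_year]
    v1 = series[end_year]
    if v0 == 0:
        return UNDEFINED_TREND
    return 100.0 * (v1 - v0) / v0 * scale_factor


def is_defined(trend: float) -> bool:
    return not math.isnan(trend)
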