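"""Scenario bundle persistence: plain-text rasters, WKT ranges, CSV tables.

A scenario directory contains:

* ``meta.yaml`` — scenario name and grid/years/legend metadata;
* ``lc_<year>.asc`` — one ESRI ASCII grid of land-cover codes per year;
* ``dem.asc`` — elevation;
* ``crosswalk.csv`` — columns ``lc_code, habitat_code`` (one row per pair,
  ``none`` for codes mapping to no habitat class);
* ``ranges.csv`` — columns ``species_id, season, wkt``;
* ``traits.csv`` — one row per species (see ``TRAIT_COLUMNS``);
* ``truth.csv`` — optional ground truth (intended category, habitat areas);
* ``models.yaml`` — density / dispersal / viability coefficients.

Loading validates grids and legend coverage and names the first offending
record of any malformed file.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely import wkt as shapely_wkt

from .demography import DensityModel, DispersalModel, ViabilityModel
from .errors import InputValidationError
from .grids import Raster, read_ascii_grid, write_ascii_grid
from .habitat import Crosswalk, LandCoverSeries, SpeciesProfile
from .synthetic import GroundTruth, ScenarioBundle, ScenarioSpec

TRAIT_COLUMNS = [
    "species_id", "taxon_class", "order_tag", "is_bat", "diet",
    "body_mass_g", "generation_length_yr", "altitude_min_m", "altitude_max_m",
    "habitat_codes", "published_category", "density_key",
]


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def save_bundle(bundle: ScenarioBundle, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = bundle.spec
    lc = bundle.landcover

    with (outdir / "meta.yaml").open("w") as fh:
        yaml.safe_dump(
            {
                "name": bundle.name,
                "years": list(lc.years),
                "legend": sorted(lc.legend),
                "nodata": int(lc.nodata),
                "cell_size": spec.cell_size,
                "grid_rows": spec.grid_rows,
                "grid_cols": spec.grid_cols,
                "seed": spec.seed,
                "crs_tag": lc.grid.crs_tag,
            },
            fh,
        )

    for i, year in enumerate(lc.years):
        write_ascii_grid(
            outdir / f"lc_{year}.asc",
            Raster(grid=lc.grid, values=lc.data[i], nodata=lc.nodata),
        )
    write_ascii_grid(outdir / "dem.asc", bundle.dem)
    bundle.crosswalk.to_csv(outdir / "crosswalk.csv")

    range_rows = []
    trait_rows = []
    for p in bundle.profiles:
        for season, geom in p.season_polygons.items():
            if geom is not None:
                range_rows.append(
                    {"species_id": p.species_id, "season": season, "wkt": geom.wkt}
                )
        trait_rows.append(
            {
                "species_id": p.species_id,
                "taxon_class": p.taxon_class,
                "order_tag": p.order_tag,
                "is_bat": p.is_bat,
                "diet": p.diet,
                "body_mass_g": p.body_mass_g,
                "generation_length_yr": p.generation_length_yr,
                "altitude_min_m": p.altitude_min_m,
                "altitude_max_m": p.altitude_max_m,
                "habitat_codes": "|".join(sorted(p.suitable_habitat_codes)),
                "published_category": p.published_category,
                "density_key": p.density_key,
            }
        )
    pd.DataFrame(range_rows).to_csv(outdir / "ranges.csv", index=False)
    pd.DataFrame(trait_rows, columns=TRAIT_COLUMNS).to_csv(
        outdir / "traits.csv", index=False
    )

    truth_rows = []
    for t in bundle.truths.values():
        row = {
            "species_id": t.species_id,
            "intended_category": t.intended_category,
            "fragment_count": t.fragment_count,
        }
        for year, a in t.esh_km2_by_year.items():
            row[f"esh_{year}"] = a
        truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)

    dm, pm, vm = bundle.density_model, bundle.dispersal_model, bundle.viability_model
    with (outdir / "models.yaml").open("w") as fh:
        yaml.safe_dump(
            {
                "density": {
                    "intercept": dm.intercept,
                    "mass_exponent": dm.mass_exponent,
                    "diet_offsets": dict(dm.diet_offsets),
                    "covariate_coefs": dict(dm.covariate_coefs),
                    "random_effects": dict(dm.random_effects),
                },
                "dispersal": {k: list(v) for k, v in pm.coefficients.items()},
                "viability": [
                    {"key": k, "p": p, "individuals": v}
                    for (k, p), v in sorted(vm.table.items())
                ],
            },
            fh,
        )
    return outdir


def load_bundle(indir) -> ScenarioBundle:
    indir = Path(indir)
    try:
        with (indir / "meta.yaml").open() as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError:
        raise InputValidationError(f"{indir}: missing meta.yaml")

    years = tuple(int(y) for y in meta["years"])
    rasters = []
    for year in years:
        path = indir / f"lc_{year}.asc"
        if not path.exists():
            raise InputValidationError(f"missing land-cover raster {path.name}")
        rasters.append(read_ascii_grid(path, crs_tag=meta.get("crs_tag", "local-equal-area-m")))
    grid = rasters[0].grid
    for year, r in zip(years, rasters):
        if not grid.matches(r.grid):
            raise InputValidationError(f"lc_{year}.asc is not on the shared grid")
    lc = LandCoverSeries(
        grid=grid,
        years=years,
        data=np.stack([r.values for r in rasters]).astype(np.int16),
        legend=frozenset(int(c) for c in meta["legend"]),
        nodata=int(meta.get("nodata", -9999)),
        meta={"name": meta.get("name", "loaded")},
    )
    dem = read_ascii_grid(indir / "dem.asc", crs_tag=grid.crs_tag, dtype=float)
    if not grid.matches(dem.grid):
        raise InputValidationError("dem.asc is not on the shared grid")

    xwalk = Crosswalk.from_csv(indir / "crosswalk.csv")
    xwalk.validate_legend(lc.legend)

    geoms: dict[str, dict] = {}
    ranges = pd.read_csv(indir / "ranges.csv")
    for i, rec in ranges.iterrows():
        try:
            geom = shapely_wkt.loads(rec["wkt"])
        except Exception as exc:
            raise InputValidationError(
                f"ranges.csv row {i} (species {rec['species_id']}): bad WKT ({exc})"
            )
        geoms.setdefault(rec["species_id"], {})[rec["season"]] = geom

    traits = pd.read_csv(indir / "traits.csv")
    profiles = []
    crosswalk_codes = frozenset().union(*xwalk.mapping.values()) if xwalk.mapping else frozenset()
    for i, rec in traits.iterrows():
        sid = rec["species_id"]
        if sid not in geoms:
            raise InputValidationError(f"traits.csv row {i}: species {sid} has no range polygon")
        try:
            profiles.append(
                SpeciesProfile(
                    species_id=sid,
                    taxon_class=rec["taxon_class"],
                    order_tag=_opt(rec.get("order_tag")) or "",
                    is_bat=bool(rec["is_bat"]),
                    diet=rec["diet"],
                    body_mass_g=float(rec["body_mass_g"]),
                    generation_length_yr=float(rec["generation_length_yr"]),
                    altitude_min_m=_opt(rec.get("altitude_min_m")),
                    altitude_max_m=_opt(rec.get("altitude_max_m")),
                    published_category=_opt(rec.get("published_category")),
                    density_key=_opt(rec.get("density_key")),
                    suitable_habitat_codes=(
                        frozenset(str(rec["habitat_codes"]).split("|"))
                        if _opt(rec.get("habitat_codes"))
                        else crosswalk_codes
                    ),
                    season_polygons=geoms[sid],
                )
            )
        except ValueError as exc:
            raise InputValidationError(f"traits.csv row {i} (species {sid}): {exc}")

    truths: dict[str, GroundTruth] = {}
    truth_path = indir / "truth.csv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path)
        esh_cols = [c for c in tdf.columns if c.startswith("esh_")]
        for _, rec in tdf.iterrows():
            truths[rec["species_id"]] = GroundTruth(
                species_id=rec["species_id"],
                esh_km2_by_year={int(c[4:]): float(rec[c]) for c in esh_cols},
                fragment_count=_opt(rec.get("fragment_count")),
                intended_category=_opt(rec.get("intended_category")),
            )

    with (indir / "models.yaml").open() as fh:
        mod = yaml.safe_load(fh)
    density_model = DensityModel(**mod["density"])
    dispersal_model = DispersalModel(
        coefficients={k: tuple(v) for k, v in mod["dispersal"].items()}
    )
    viability_model = ViabilityModel(
        table={(e["key"], e["p"]): e["individuals"] for e in mod["viability"]}
    )

    spec = ScenarioSpec(
        grid_rows=meta["grid_rows"],
        grid_cols=meta["grid_cols"],
        cell_size=meta["cell_size"],
        years=years,
        legend=tuple(sorted(lc.legend)),
        seed=meta.get("seed", 0),
    )
    return ScenarioBundle(
        name=meta.get("name", "loaded"),
        spec=spec,
        landcover=lc,
        dem=dem,
        crosswalk=xwalk,
        profiles=profiles,
        truths=truths,
        density_model=density_model,
        dispersal_model=dispersal_model,
        viability_model=viability_model,
    )
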