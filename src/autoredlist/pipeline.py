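"""Per-species metric computation and batch assessment orchestration.

``compute_metrics`` turns one species' inputs (range polygons, land-cover
series, crosswalk, elevation) into the :class:`~autoredlist.engine.MetricsBundle`
the criteria engine consumes; ``run_batch`` maps it over a scenario,
aggregates an assessment table, computes agreement statistics against
published categories when present, and emits a deterministic run manifest.
``sweep_fragmentation`` re-runs the strict fragmentation mode under a list
of alternative smallness definitions and tabulates threatened counts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from . import __version__
from .demography import (
    DensityModel,
    DispersalModel,
    ViabilityModel,
    median_dispersal,
    population_size,
    predict_density,
)
from .engine import (
    CRITERIA,
    Assessment,
    MetricsBundle,
    ThresholdConfig,
    assess,
)
from .errors import UnsupportedTaxonError
from .evaluation import agreement_report, split_dd
from .fragmentation import (
    SmallnessRule,
    clump,
    label_fragments,
    severe_fragmentation,
)
from .habitat import (
    LandCoverSeries,
    Crosswalk,
    SpeciesProfile,
    build_esh,
    compute_eoo,
    criterion_window,
    percent_change,
    trend_window,
    upscale_aoo,
)
from .grids import Raster


@dataclass(frozen=True)
class AssessmentOptions:
    """Switches that select between documented operating modes."""

    mode: str = "decline_only"  # or "frag_and_decline"
    smallness_rule: SmallnessRule = field(
        default_factory=lambda: SmallnessRule(kind="area_lt", threshold=100.0)
    )
    adjacency: str = "queen"
    coarse_cell_size: float = 2000.0  # metres, the AOO reference grid
    occupancy: float = 1.0
    a2_source: str = "population"  # or "esh"

    def describe(self) -> dict:
        return {
            "mode": self.mode,
            "smallness_rule": self.smallness_rule.rule_id,
            "adjacency": self.adjacency,
            "coarse_cell_size_m": self.coarse_cell_size,
            "occupancy": self.occupancy,
            "a2_source": self.a2_source,
        }


def compute_metrics(
    profile: SpeciesProfile,
    lc: LandCoverSeries,
    xwalk: Crosswalk,
    dem: Optional[Raster],
    density_model: Optional[DensityModel],
    dispersal_model: Optional[DispersalModel],
    viability_model: Optional[ViabilityModel] = None,
    options: Optional[AssessmentOptions] = None,
    thresholds: Optional[ThresholdConfig] = None,
) -> MetricsBundle:
    """All engine inputs for one species.

    Population-based quantities are computed for non-bats with a density
    model; otherwise the habitat-area series stands in where allowed
    (A2 trend) and population criteria are left not-evaluated. The
    fragmentation verdict is computed on the final year.
    """
    options = options or AssessmentOptions()
    thresholds = thresholds or ThresholdConfig()
    first, last = lc.years[0], lc.years[-1]
    gl = profile.generation_length_yr

    eoo = compute_eoo(profile)
    esh = build_esh(profile, lc, xwalk, dem)
    extras: dict = {"eoo_km2": eoo}
    if esh.empty_flag:
        return MetricsBundle(
            species_id=profile.species_id,
            taxon_class=profile.taxon_class,
            is_bat=profile.is_bat,
            generation_length_yr=gl,
            eoo_km2=eoo,
            zero_esh=True,
            extras=extras,
        )

    areas = esh.area_series()
    aoo = upscale_aoo(esh, last, options.coarse_cell_size)
    extras["esh_km2_by_year"] = areas
    extras["aoo_km2"] = aoo

    density = None
    pop_by_year: Optional[dict[int, float]] = None
    if density_model is not None and not profile.is_bat:
        density = predict_density(density_model, profile)
        pop_by_year = {
            y: population_size(esh, y, density, occupancy=options.occupancy)
            for y in lc.years
        }
        extras["density_per_km2"] = density
        extras["population_by_year"] = pop_by_year

    # A2 window and the habitat-decline subcriterion share one time frame
    start, factor = trend_window(gl, first, last)
    esh_trend = percent_change(areas, start, last, factor)
    use_population = options.a2_source == "population" and pop_by_year is not None
    a2_trend = (
        percent_change(pop_by_year, start, last, factor) if use_population else esh_trend
    )
    decline_biii = (not math.isnan(esh_trend)) and (
        esh_trend <= -thresholds.biii_decline_tolerance_pct
    )
    extras["esh_trend_pct"] = esh_trend
    extras["a2_window"] = (start, factor)

    c1_declines: dict[str, float] = {}
    if pop_by_year is not None:
        for cat, (floor_yr, n_gen) in thresholds.c1_windows.items():
            s, f = criterion_window(floor_yr, n_gen, gl, first, last)
            c1_declines[cat] = -percent_change(pop_by_year, s, last, f)

    severe_frag: Optional[bool] = None
    if not profile.is_bat and dispersal_model is not None:
        frags = label_fragments(esh, last, adjacency=options.adjacency)
        if density is not None:
            cell_area = esh.grid.cell_area_km2
            frag_areas = frags.areas()
            frags.populations = {
                fid: density * a * options.occupancy for fid, a in frag_areas.items()
            }
        dispersal_km = median_dispersal(dispersal_model, profile)
        clumps = clump(frags, dispersal_km)
        try:
            verdict = severe_fragmentation(
                clumps,
                options.smallness_rule,
                areas[last],
                profile=profile,
                viability_model=viability_model,
            )
            severe_frag = verdict.severe
            extras["fragmentation"] = {
                "n_fragments": frags.n_fragments,
                "n_clumps": clumps.n_clumps,
                "small_area_fraction": verdict.small_area_fraction,
                "rule_id": verdict.rule_id,
                "dispersal_km": dispersal_km,
            }
        except (UnsupportedTaxonError, ValueError) as exc:
            extras["fragmentation_skipped"] = str(exc)

    threat = profile.threat_flag if profile.threat_flag is not None else decline_biii

    return MetricsBundle(
        species_id=profile.species_id,
        taxon_class=profile.taxon_class,
        is_bat=profile.is_bat,
        generation_length_yr=gl,
        eoo_km2=eoo,
        aoo_km2=aoo,
        population=None if pop_by_year is None else pop_by_year[last],
        a2_trend_pct=a2_trend,
        a2_source="population" if use_population else "esh",
        c1_decline_pct=c1_declines,
        severe_frag=severe_frag,
        decline_biii=decline_biii,
        threat_flag=bool(threat),
        zero_esh=False,
        extras=extras,
    )


@dataclass
class BatchResult:
    assessments: dict[str, Assessment]
    table: pd.DataFrame
    agreement: Optional[dict]
    dd_report: Optional[pd.DataFrame]
    manifest: dict


def _assessment_row(a: Assessment, profile: SpeciesProfile) -> dict:
    m = a.metrics
    row = {
        "species_id": a.species_id,
        "taxon_class": profile.taxon_class,
        "is_bat": profile.is_bat,
        "status": a.status,
        "final_category": a.final_category,
        "qualifying": ";".join(a.qualifying),
        "published_category": profile.published_category,
        "eoo_km2": m.eoo_km2 if m else None,
        "aoo_km2": m.aoo_km2 if m and not m.zero_esh else None,
        "population": m.population if m else None,
        "a2_trend_pct": m.a2_trend_pct if m else None,
        "decline_biii": m.decline_biii if m else None,
        "severe_frag": m.severe_frag if m else None,
        "flags": ";".join(a.flags),
    }
    for c in CRITERIA:
        row[c] = a.criteria[c].category if c in a.criteria else None
    return row


def run_batch(
    bundle,
    thresholds: Optional[ThresholdConfig] = None,
    options: Optional[AssessmentOptions] = None,
) -> BatchResult:
    """Assess every species in a scenario bundle.

    Zero-ESH species are carried through with status ``excluded`` (never
    silently dropped) and kept out of the agreement statistics, as are
    species published as data deficient — those get their own report of
    predictions. Identical inputs and options yield identical outputs.
    """
    thresholds = thresholds or ThresholdConfig()
    thresholds.validate()
    options = options or AssessmentOptions()

    assessments: dict[str, Assessment] = {}
    rows = []
    for profile in bundle.profiles:
        metrics = compute_metrics(
            profile,
            bundle.landcover,
            bundle.crosswalk,
            bundle.dem,
            density_model=bundle.density_model,
            dispersal_model=bundle.dispersal_model,
            viability_model=bundle.viability_model,
            options=options,
            thresholds=thresholds,
        )
        a = assess(metrics, thresholds, mode=options.mode)
        assessments[profile.species_id] = a
        rows.append(_assessment_row(a, profile))

    table = pd.DataFrame(rows)
    assessed = table[table["status"] == "assessed"]

    agreement = None
    dd_report = None
    with_pub = assessed[assessed["published_category"].notna()]
    if len(with_pub):
        rankable, dd = split_dd(with_pub, "published_category")
        if len(dd):
            dd_report = dd[["species_id", "final_category", "qualifying"]].copy()
        if len(rankable) >= 2:
            agreement = agreement_report(
                rankable["published_category"].tolist(),
                rankable["final_category"].tolist(),
            )

    cfg_blob = json.dumps(
        {"options": options.describe(), "thresholds": thresholds.__dict__},
        sort_keys=True, default=str,
    )
    manifest = {
        "package_version": __version__,
        "scenario": getattr(bundle, "name", "unnamed"),
        "config_hash": hashlib.sha256(cfg_blob.encode()).hexdigest()[:16],
        "options": options.describe(),
        "n_species": len(bundle.profiles),
        "n_assessed": int((table["status"] == "assessed").sum()),
        "n_excluded": int((table["status"] == "excluded").sum()),
        "n_threatened": int(
            assessed["final_category"].isin(["VU", "EN", "CR"]).sum()
        ),
    }
    return BatchResult(
        assessments=assessments,
        table=table,
        agreement=agreement,
        dd_report=dd_report,
        manifest=manifest,
    )


def threatened_set(result: BatchResult) -> frozenset[str]:
    t = result.table
    mask = (t["status"] == "assessed") & t["final_category"].isin(["VU", "EN", "CR"])
    return frozenset(t.loc[mask, "species_id"])


def sweep_fragmentation(
    bundle,
    rules: list[SmallnessRule],
    thresholds: Optional[ThresholdConfig] = None,
    options: Optional[AssessmentOptions] = None,
) -> pd.DataFrame:
    """Threatened counts under strict fragmentation mode, one row per rule.

    MVP-based rules are defined for mammals only; for those rules birds
    are excluded from the count and the row is annotated.
    """
    if not rules:
        raise ValueError("rule list must not be empty")
    options = options or AssessmentOptions()
    rows = []
    for rule in rules:
        opts = replace(options, mode="frag_and_decline", smallness_rule=rule)
        result = run_batch(bundle, thresholds=thresholds, options=opts)
        t = result.table
        scope = t[t["status"] == "assessed"]
        note = ""
        if rule.kind == "mvp":
            scope = scope[scope["taxon_class"] == "mammal"]
            note = "mammals only"
        rows.append(
            {
                "rule_id": rule.rule_id,
                "n_in_scope": len(scope),
                "n_threatened": int(scope["final_category"].isin(["VU", "EN", "CR"]).sum()),
                "note": note,
            }
        )
    return pd.DataFrame(rows)
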