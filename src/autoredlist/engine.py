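"""The Red List criteria engine: A2, B1, B2, C1, D1, D2.

Each criterion maps a species' computed metrics onto one of the threat
categories CR (critically endangered), EN (endangered), VU (vulnerable)
or LC (least concern); the species is finally listed in the most
threatened category under which it qualifies. Near threatened is never
emitted — it has no explicit quantitative thresholds, so non-qualifying
species are reported as LC (read: LC/NT).

Boundary semantics follow the IUCN convention: reduction/decline
thresholds are inclusive (a reduction of exactly 30% qualifies for VU
under A2) while size and population thresholds are strict (a population
of exactly 250 fails the EN cap "fewer than 250" but meets VU's
"fewer than 1,000").

Criteria handled and their gates:

* **A2** — population reduction over max(10 years, 3 generations).
* **B1/B2** — small EOO/AOO plus subcriteria: biii (continuing decline in
  habitat area/extent/quality) always required; subcriterion a (severe
  fragmentation) additionally required in mode ``frag_and_decline``.
* **C1** — small population plus a continuing decline at a
  window-specific rate (≥25% in max(3 yr, 1 GL) for CR, ≥20% in
  max(5 yr, 2 GL) for EN, ≥10% in max(10 yr, 3 GL) for VU).
* **D1** — very small population; **D2** — very small AOO with plausible
  threats (VU only).

Bats are assessed under B1/B2 only (no density or dispersal predictions),
and species whose habitat preferences produce no suitable habitat at all
are excluded rather than scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

CATEGORIES = ("LC", "VU", "EN", "CR")
SEVERITY = {"LC": 0, "VU": 1, "EN": 2, "CR": 3}
CRITERIA = ("A2", "B1", "B2", "C1", "D1", "D2")

NOT_EVALUATED = "NE"


@dataclass
class ThresholdConfig:
    """Quantitative thresholds for the six criteria (editable defaults)."""

    a2_reduction_pct: dict[str, float] = field(
        default_factory=lambda: {"CR": 80.0, "EN": 50.0, "VU": 30.0}
    )
    b1_eoo_km2: dict[str, float] = field(
        default_factory=lambda: {"CR": 100.0, "EN": 5000.0, "VU": 20000.0}
    )
    b2_aoo_km2: dict[str, float] = field(
        default_factory=lambda: {"CR": 10.0, "EN": 500.0, "VU": 2000.0}
    )
    c1_population: dict[str, float] = field(
        default_factory=lambda: {"CR": 250.0, "EN": 2500.0, "VU": 10000.0}
    )
    c1_decline_pct: dict[str, float] = field(
        default_factory=lambda: {"CR": 25.0, "EN": 20.0, "VU": 10.0}
    )
    #: (floor years, number of generations) per category for the C1 decline window
    c1_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CR": (3.0, 1.0), "EN": (5.0, 2.0), "VU": (10.0, 3.0)}
    )
    d1_population: dict[str, float] = field(
        default_factory=lambda: {"CR": 50.0, "EN": 250.0, "VU": 1000.0}
    )
    d2_aoo_km2: float = 20.0
    #: ESH-area decline (%) over the A2 window that counts as continuing
    #: decline for subcriterion biii; absorbs raster noise.
    biii_decline_tolerance_pct: float = 0.5

    def validate(self) -> None:
        for name, d, increasing in (
            ("a2_reduction_pct", self.a2_reduction_pct, False),
            ("b1_eoo_km2", self.b1_eoo_km2, True),
            ("b2_aoo_km2", self.b2_aoo_km2, True),
            ("c1_population", self.c1_population, True),
            ("c1_decline_pct", self.c1_decline_pct, False),
            ("d1_population", self.d1_population, True),
        ):
            vals = [d["CR"], d["EN"], d["VU"]]
            ok = vals[0] < vals[1] < vals[2] if increasing else vals[0] > vals[1] > vals[2]
            if not ok:
                raise ValueError(f"{name} thresholds are not strictly ordered: {vals}")

    def to_yaml(self, path) -> None:
        data = {
            "a2_reduction_pct": self.a2_reduction_pct,
            "b1_eoo_km2": self.b1_eoo_km2,
            "b2_aoo_km2": self.b2_aoo_km2,
            "c1_population": self.c1_population,
            "c1_decline_pct": self.c1_decline_pct,
            "c1_windows": {k: list(v) for k, v in self.c1_windows.items()},
            "d1_population": self.d1_population,
            "d2_aoo_km2": self.d2_aoo_km2,
            "biii_decline_tolerance_pct": self.biii_decline_tolerance_pct,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "c1_windows" in data:
            data["c1_windows"] = {k: tuple(v) for k, v in data["c1_windows"].items()}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class CriterionResult:
    criterion: str
    category: str  # LC/VU/EN/CR or NE (not evaluated)
    details: dict = field(default_factory=dict)

    @property
    def evaluated(self) -> bool:
        return self.category != NOT_EVALUATED

    @property
    def severity(self) -> int:
        return SEVERITY.get(self.category, 0)


@dataclass
class MetricsBundle:
    """Computed inputs to the criteria engine for one species."""

    species_id: str
    taxon_class: str = "mammal"
    is_bat: bool = False
    generation_length_yr: float = 1.0
    eoo_km2: float = math.inf
    aoo_km2: float = math.inf
    population: Optional[float] = None
    a2_trend_pct: float = math.nan  # % change (negative = decline)
    a2_source: str = "population"
    c1_decline_pct: Mapping[str, float] = field(default_factory=dict)  # positive = decline
    severe_frag: Optional[bool] = None
    decline_biii: bool = False
    threat_flag: bool = False
    zero_esh: bool = False
    extras: dict = field(default_factory=dict)


@dataclass
class Assessment:
    species_id: str
    status: str  # "assessed" | "excluded"
    final_category: Optional[str]
    criteria: dict[str, CriterionResult]
    qualifying: tuple[str, ...]
    flags: tuple[str, ...]
    metrics: Optional[MetricsBundle] = None


def _band_reduction(reduction: float, thresholds: dict[str, float]) -> str:
    """Inclusive reduction thresholds: exactly meeting a rate qualifies."""
    for cat in ("CR", "EN", "VU"):
        if reduction >= thresholds[cat]:
            return cat
    return "LC"


def _band_size(size: float, thresholds: dict[str, float]) -> str:
    """Strict size thresholds: the value must fall below the cap."""
    for cat in ("CR", "EN", "VU"):
        if size < thresholds[cat]:
            return cat
    return "LC"


def apply_A2(trend_pct: float, cfg: ThresholdConfig) -> CriterionResult:
    """Population reduction over the longer of 10 years or 3 generations."""
    if math.isnan(trend_pct):
        return CriterionResult("A2", NOT_EVALUATED, {"reason": "undefined trend"})
    reduction = -trend_pct
    cat = _band_reduction(reduction, cfg.a2_reduction_pct)
    return CriterionResult("A2", cat, {"reduction_pct": reduction})


def apply_B(
    size_km2: float,
    size_axis: str,
    severe_frag: Optional[bool],
    decline: bool,
    mode: str,
    cfg: ThresholdConfig,
    is_bat: bool = False,
) -> CriterionResult:
    """Small EOO (B1) or AOO (B2) gated by the required subcriteria.

    ``decline_only`` requires subcriterion biii; ``frag_and_decline``
    additionally requires subcriterion a (severe fragmentation). Bats have
    no dispersal prediction, so in ``frag_and_decline`` mode they fall
    back to the decline gate with an audit flag.
    """
    if size_axis not in ("B1", "B2"):
        raise ValueError("size_axis must be B1 or B2")
    if mode not in ("decline_only", "frag_and_decline"):
        raise ValueError(f"unknown B mode {mode!r}")
    if size_km2 < 0:
        raise ValueError("size must be non-negative")
    thresholds = cfg.b1_eoo_km2 if size_axis == "B1" else cfg.b2_aoo_km2
    candidate = _band_size(size_km2, thresholds)
    details: dict = {"size_km2": size_km2, "candidate": candidate, "mode": mode}
    gate = decline
    if mode == "frag_and_decline":
        if is_bat or severe_frag is None:
            details["fallback"] = "no fragmentation verdict; decline gate only"
        else:
            gate = decline and severe_frag
    cat = candidate if (candidate != "LC" and gate) else "LC"
    return CriterionResult(size_axis, cat, details)


def apply_C1(
    population: Optional[float],
    declines_pct: Mapping[str, float],
    cfg: ThresholdConfig,
) -> CriterionResult:
    """Small and declining population.

    ``declines_pct`` holds the observed decline (positive %) over each
    category's own window. The highest category whose population cap and
    decline rate are both met wins.
    """
    if population is None:
        return CriterionResult("C1", NOT_EVALUATED, {"reason": "no population estimate"})
    if population < 0:
        raise ValueError("population must be non-negative")
    for cat in ("CR", "EN", "VU"):
        decline = declines_pct.get(cat, math.nan)
        if math.isnan(decline):
            return CriterionResult("C1", NOT_EVALUATED, {"reason": "undefined trend"})
        if population < cfg.c1_population[cat] and decline >= cfg.c1_decline_pct[cat]:
            return CriterionResult(
                "C1", cat, {"population": population, "decline_pct": decline}
            )
    return CriterionResult("C1", "LC", {"population": population})


def apply_D(
    population: Optional[float],
    aoo_km2: float,
    threat: bool,
    cfg: ThresholdConfig,
) -> CriterionResult:
    """Very small population (D1) or very small AOO with threats (D2, VU only)."""
    d1 = "LC"
    if population is not None:
        if population < 0:
            raise ValueError("population must be non-negative")
        d1 = _band_size(population, cfg.d1_population)
    d2 = "VU" if (aoo_km2 < cfg.d2_aoo_km2 and threat) else "LC"
    cat = d1 if SEVERITY[d1] >= SEVERITY[d2] else d2
    crit = "D1" if SEVERITY[d1] >= SEVERITY[d2] else "D2"
    return CriterionResult(
        crit, cat, {"population": population, "aoo_km2": aoo_km2, "threat": threat}
    )


def assess(
    metrics: MetricsBundle,
    cfg: Optional[ThresholdConfig] = None,
    mode: str = "decline_only",
) -> Assessment:
    """Run every applicable criterion and keep the most threatened category."""
    cfg = cfg or ThresholdConfig()
    flags: list[str] = []
    if metrics.zero_esh:
        return Assessment(
            species_id=metrics.species_id,
            status="excluded",
            final_category=None,
            criteria={},
            qualifying=(),
            flags=("zero_esh",),
            metrics=metrics,
        )

    results: dict[str, CriterionResult] = {}
    if metrics.is_bat:
        flags.append("bat_restricted")
        results["A2"] = CriterionResult("A2", NOT_EVALUATED, {"reason": "bat"})
        results["C1"] = CriterionResult("C1", NOT_EVALUATED, {"reason": "bat"})
        results["D1"] = CriterionResult("D1", NOT_EVALUATED, {"reason": "bat"})
        results["D2"] = CriterionResult("D2", NOT_EVALUATED, {"reason": "bat"})
    else:
        results["A2"] = apply_A2(metrics.a2_trend_pct, cfg)
        results["C1"] = apply_C1(metrics.population, metrics.c1_decline_pct, cfg)
        d1 = "LC"
        if metrics.population is not None:
            d1 = _band_size(metrics.population, cfg.d1_population)
        d2 = "VU" if (metrics.aoo_km2 < cfg.d2_aoo_km2 and metrics.threat_flag) else "LC"
        results["D1"] = CriterionResult("D1", d1, {"population": metrics.population})
        results["D2"] = CriterionResult(
            "D2", d2, {"aoo_km2": metrics.aoo_km2, "threat": metrics.threat_flag}
        )

    results["B1"] = apply_B(
        metrics.eoo_km2, "B1", metrics.severe_frag, metrics.decline_biii,
        mode, cfg, is_bat=metrics.is_bat,
    )
    results["B2"] = apply_B(
        metrics.aoo_km2, "B2", metrics.severe_frag, metrics.decline_biii,
        mode, cfg, is_bat=metrics.is_bat,
    )

    if any(r.category == NOT_EVALUATED and r.details.get("reason") == "undefined trend"
           for r in results.values()):
        flags.append("undefined_trend")
    flags.append(f"a2_source:{metrics.a2_source}")

    final_sev = max(r.severity for r in results.values() if r.evaluated)
    final = CATEGORIES[final_sev]
    qualifying = tuple(
        c for c in CRITERIA
        if results[c].evaluated and results[c].severity == final_sev and final != "LC"
    )
    return Assessment(
        species_id=metrics.species_id,
        status="assessed",
        final_category=final,
        criteria=results,
        qualifying=qualifying,
        flags=tuple(flags),
        metrics=metrics,
    )
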