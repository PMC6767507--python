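"""Trait-based demographic predictors: density, population, dispersal, MVP.

The assessment needs three quantities that are not observable from land
cover alone: population density (individuals/km², to turn habitat area
into population size), median natal dispersal distance (km, to decide
which habitat fragments are demographically connected), and a minimum
viable population (individuals, one of the alternative "small fragment"
definitions for mammals). All three follow simple allometric shapes on
body mass, with coefficients supplied through configuration — the package
defines the plug-in points and ships documented toy defaults for testing,
not refitted field models.

Density follows a log10–log10 allometry with additive adjustments::

    log10 D = intercept + slope · log10(mass_g) + diet_offset
              + Σ covariate_coefs · covariates + random_effect(taxon key)

Dispersal is a power law per taxon class, distance_km = a · mass_g^b.
MVP is a lookup keyed by (taxon key, p), where p is an assumed proportion
of the maximum population growth rate in {0.2, 0.4, 0.6, 0.8, 1.0};
slower-growing populations (smaller p) need larger MVPs.

None of the predictors apply to bats: their densities are driven by roost
locations rather than habitat area, so bats are assessed under the range
criteria only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import UnsupportedTaxonError
from .habitat import EshSeries, SpeciesProfile

MVP_P_VALUES = (0.2, 0.4, 0.6, 0.8, 1.0)


def _require_not_bat(profile: SpeciesProfile, what: str) -> None:
    if profile.is_bat:
        raise UnsupportedTaxonError(
            f"{what} is not predicted for bats ({profile.species_id}); "
            "bats are assessed under criteria B1/B2 only"
        )


@dataclass
class DensityModel:
    """Allometric population-density model (individuals/km²)."""

    intercept: float
    mass_exponent: float
    diet_offsets: dict[str, float] = field(default_factory=dict)
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    random_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class DispersalModel:
    """Median natal dispersal distance (km) as a·mass_g^b per taxon class."""

    coefficients: dict[str, tuple[float, float]]  # taxon_class -> (a, b)


@dataclass
class ViabilityModel:
    """Minimum-viable-population lookup for mammals.

    ``table`` maps (taxon_key, p) to individuals; for a fixed taxon key the
    MVP must be non-increasing in p (higher assumed growth rate → smaller
    viable population).
    """

    table: dict[tuple[str, float], float]
    p_values: tuple[float, ...] = MVP_P_VALUES

    def validate(self) -> None:
        keys = {k for k, _ in self.table}
        for key in keys:
            vals = [self.table[(key, p)] for p in self.p_values if (key, p) in self.table]
            if any(b > a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"MVP not non-increasing in p for taxon key {key!r}")


def predict_density(
    model: DensityModel,
    profile: SpeciesProfile,
    cell_covariates: Optional[Mapping[str, float]] = None,
) -> float:
    """Predicted population density (individuals/km²) for one species.

    Pure function of the model and profile; absent covariates and unknown
    diet/random-effect keys contribute zero on the log scale.
    """
    _require_not_bat(profile, "population density")
    if profile.body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    log10d = (
        model.intercept
        + model.mass_exponent * math.log10(profile.body_mass_g)
        + model.diet_offsets.get(profile.diet, 0.0)
        + model.random_effects.get(profile.density_key or profile.order_tag, 0.0)
    )
    if cell_covariates:
        for name, coef in model.covariate_coefs.items():
            log10d += coef * cell_covariates.get(name, 0.0)
    return 10.0**log10d


def population_size(
    esh: EshSeries,
    year: int,
    density,
    occupancy: float = 1.0,
) -> float:
    """Population within the ESH (mature individuals).

    ``density`` is either a scalar (individuals/km², applied uniformly) or
    an array on the ESH grid. The default ``occupancy=1`` encodes the
    deliberately optimistic assumption that suitable habitat is fully
    occupied; lowering it scales the estimate for sensitivity analyses.
    """
    mask = esh.mask(year)
    cell_area = esh.grid.cell_area_km2
    if np.isscalar(density):
        total = float(density) * int(mask.sum()) * cell_area
    else:
        density = np.asarray(density, dtype=float)
        if density.shape != mask.shape:
            raise ValueError("density field shape does not match the grid")
        total = float(density[mask].sum()) * cell_area
    return total * occupancy


def median_dispersal(model: DispersalModel, profile: SpeciesProfile) -> float:
    """Median natal dispersal distance (km) from the taxon-class allometry."""
    _require_not_bat(profile, "dispersal distance")
    if profile.body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    try:
        a, b = model.coefficients[profile.taxon_class]
    except KeyError:
        raise UnsupportedTaxonError(f"no dispersal allometry for {profile.taxon_class!r}")
    return a * profile.body_mass_g**b


def mvp(model: ViabilityModel, profile: SpeciesProfile, p: float) -> float:
    """Minimum viable population (individuals) for a mammal at growth proportion p."""
    if profile.taxon_class != "mammal":
        raise UnsupportedTaxonError(
            "population viability targets are available for mammals only"
        )
    if p not in model.p_values:
        raise ValueError(f"p must be one of {model.p_values}, got {p}")
    key = (profile.density_key or profile.order_tag, p)
    if key not in model.table:
        raise KeyError(f"no MVP entry for {key!r}")
    return model.table[key]


# ---------------------------------------------------------------------------
# Toy defaults — plug-in coefficients for tests and synthetic scenarios only.


def toy_density_model() -> DensityModel:
    """A mass-only density allometry with round-number coefficients."""
    return DensityModel(
        intercept=2.0,
        mass_exponent=-0.75,
        diet_offsets={"carnivore": -0.3, "herbivore": 0.2, "omnivore": 0.0},
    )


def constant_density_model(density: float) -> DensityModel:
    """Density model that predicts a fixed density regardless of traits."""
    return DensityModel(intercept=math.log10(density), mass_exponent=0.0)


def toy_dispersal_model() -> DispersalModel:
    """Kilometre-scale dispersal for gram-to-kilogram body masses."""
    return DispersalModel(coefficients={"bird": (1.0, 0.13), "mammal": (0.5, 0.2)})


def toy_viability_model() -> ViabilityModel:
    """A small MVP lookup with the required monotone structure."""
    base = {0.2: 5000.0, 0.4: 3000.0, 0.6: 1800.0, 0.8: 1000.0, 1.0: 600.0}
    table = {}
    for key in ("default", "rodent-like", "carnivore-like"):
        scale = {"default": 1.0, "rodent-like": 0.4, "carnivore-like": 1.6}[key]
        for p, v in base.items():
            table[(key, p)] = v * scale
    return ViabilityModel(table=table)
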