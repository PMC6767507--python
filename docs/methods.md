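# Methods

This note documents the model choices, parameters, and numerical
conventions behind the assessment pipeline, and what the synthetic test
conditions do and do not demonstrate about real data.

## Spatial conventions

All computation happens on one shared equal-area grid in metres. Inputs
must arrive already projected (the projection is carried as a tag that
rasters and polygon layers must agree on); the package validates the tag
and never reprojects. Cell membership is decided by the cell-center
point throughout — a cell belongs to a polygon iff its center does, and
a fine cell belongs to the coarse occupancy cell containing its center,
with the coarse grid anchored at the fine-grid origin. The same rule on
both sides keeps fine→polygon and fine→coarse assignment consistent and
well defined even when the coarse cell size (default 2,000 m) is not an
integer multiple of the fine cell (e.g. ~300-m satellite products).

Rasters travel as ESRI ASCII grids and ranges as WKT in CSV: plain-text
formats that any GIS reads, chosen so scenario directories are fully
inspectable and diffable.

## Habitat model

A cell is suitable in year *t* when three independent masks agree: the
range mask, the crosswalked land-cover mask (the cell's class maps to at
least one of the species' suitable level-2 habitat codes), and the
altitude mask (only applied when the species has coded limits — absent
limits mean no altitude constraint). Species whose preferences match no
land cover anywhere in their range in any year are flagged
(`empty_flag`) and carried through the batch with status `excluded`
rather than dropped: an empty ESH almost always signals a coding or
crosswalk error, not a genuinely extinct habitat.

AOO is an upper bound by design (any touched coarse cell counts in
full), mirroring the standard harmonization of occupancy estimates to a
2 × 2 km reference scale.

## Trend windows

Criterion time windows have the form max(floor, k·GL) years ending at
the last mapped year (A2: floor 10, k = 3; C1: (3, 1), (5, 2), (10, 3)
for CR/EN/VU). An annual series mapped for years y₀…y₁ is counted as
spanning n = y₁ − y₀ + 1 years. If the window fits, the change is taken
over the trailing sub-window unscaled (start year clamped to y₀); if it
is longer, the change over the full span is rescaled linearly by
window/n. The linear rescaling — rather than fitting an exponential
rate and extrapolating — is deliberate: it is transparent, monotone,
and makes no claim about the functional form of decline beyond the
observed series. A zero value at the window start makes the trend
undefined; the dependent criteria (A2, C1) are then reported
not-evaluated with an audit flag instead of silently passing.

## Demographic predictors

Density, dispersal and minimum-viable-population (MVP) predictors are
model *shapes* with coefficients supplied through configuration:

* density: log₁₀D = intercept + slope·log₁₀(mass g) + diet offset +
  covariate terms + taxon random-effect offset, in individuals/km²;
* dispersal: median natal dispersal distance = a·massᵇ km, per taxon
  class;
* MVP: lookup keyed by (taxon key, p) with p ∈ {0.2, 0.4, 0.6, 0.8, 1.0}
  the assumed proportion of maximum population growth rate, validated to
  be non-increasing in p.

The shipped defaults (`toy_*` constructors: intercept 2, slope −0.75,
diet offsets ±0.2–0.3; dispersal (1.0, 0.13) for birds and (0.5, 0.2)
for mammals; a three-taxon MVP table from 600 to 8,000 individuals) are
round-number stand-ins on realistic scales for gram-to-kilogram body
masses. They exist so the pipeline and tests run out of the box; any
real analysis must plug in fitted coefficients via `models.yaml`. None
of the predictors apply to bats, whose roost-driven clumped densities
break the habitat-area × density logic; bats are therefore assessed
under the range criteria (B1/B2) only.

Population estimates assume the ESH fully occupied (occupancy ω = 1)
and all individuals mature — both deliberately optimistic, so predicted
categories err toward under- rather than over-listing; ω is exposed for
sensitivity analyses.

## Fragmentation

Fragments are connected components of the suitability raster; adjacency
defaults to queen (8-neighbor) and is switchable to rook, with the
choice recorded in output metadata. Fragment-to-fragment distance is
approximated as the minimum distance between suitable-cell centers
minus one cell size, floored at zero — an edge-to-edge proxy biased by
less than one cell diagonal, far cheaper than exact polygon-boundary
distance (which is not offered; the approximation is documented rather
than presented as exact geometry). Clumps are the transitive closure of
"within one median dispersal distance"; landscape barriers are ignored.

A range is severely fragmented when clumps classified small hold more
than 50% of the ESH *and* there are at least two clumps — a single
clump contains the entire semi-connected population, so smallness
without isolation is not fragmentation. Small is deliberately plural:
area < 100 km², fewer than a fixed number of individuals, or below an
MVP target (mammals only). Under the individuals-based definitions the
verdict is monotone in the threshold: raising the cutoff can only
reclassify more clumps as small, never fewer, so threatened counts in a
rule sweep are non-decreasing in the threshold. This direction follows
necessarily from the definition of *small*.

## Criteria engine

Thresholds ship as editable configuration with the IUCN standard
defaults (A2 reductions 80/50/30%; B1 EOO 100/5,000/20,000 km²; B2 AOO
10/500/2,000 km²; C1 caps 250/2,500/10,000 with window declines
25/20/10%; D1 50/250/1,000; D2 AOO 20 km²). Boundary semantics are
fixed and covered by tests: reduction/decline thresholds are inclusive
(≥), size and population thresholds strict (<), so a population of
exactly 250 is VU, not EN.

Criterion B requires subcriterion biii (continuing habitat decline,
operationalized as ESH loss exceeding a 0.5% tolerance over the A2
window — the tolerance absorbs rasterization noise and is
configurable). Two modes handle subcriterion a: the default
`decline_only` reports fragmentation separately, while
`frag_and_decline` additionally requires a severe-fragmentation
verdict; both are always computable because the fragmentation verdict
is produced regardless of mode. Bats, lacking a dispersal prediction,
fall back to the decline gate in strict mode with an audit flag.

A2 and C1 use the population series when a density model is available
and the ESH-area series otherwise (always for bats); the source is
recorded per species. The D2 "plausible threats" gate defaults to the
observed habitat decline and can be overridden per species. The final
category is the maximum severity over evaluated criteria, with the
qualifying criteria listed.

## Synthetic scenarios

The generator fabricates what the method consumes: rectangular habitat
blocks (or scattered cells) hitting an exact initial habitat fraction,
eroded edge-inward (or by random dropout) to track a geometric loss
schedule exactly — year *t* holds round(initial·(1 − r)^(t−t₀)) cells —
plus a smooth gradient DEM and species whose ranges are convex hulls of
fragment subsets. All randomness flows from one integer seed; outputs
are bit-identical across runs.

The default batch (50 species, 200 × 200 km, 16 blocks, 1%/yr loss,
1996–2015) was chosen so every criterion and both fragmentation modes
engage: small-range species qualify under B, long-generation species
trigger the trend rescaling, heavy species get low allometric densities
and hit D1/C1, a bat fraction exercises the range-only path, and a few
species receive habitat codes absent from the landscape to exercise the
exclusion rule. Published categories are the construction-implied
category perturbed by seeded noise (±1 category at 15% each, 6% DD,
some LC labelled NT), emulating assessor disagreement so the agreement
statistics are non-trivial. The engineered single-criterion scenarios
pin one criterion each: an 85% loss over a 24-year window with GL = 8
(A2→CR), 40 individuals (D1→CR), a ~200 km² block declining slowly
(B2→EN), and ~8,400 individuals declining 12% over ten years (C1→VU),
plus a stable control (LC).

What passing these tests shows: the measurement pipeline (rasters →
metrics → categories) reproduces the quantities the constructions imply
at the thresholds' boundary semantics, deterministically. What it does
not show: performance on real land-cover data, whose legends are noisy,
whose habitat crosswalks are many-to-many and contested, and where
species occupancy, detectability, and non-habitat threats (exploitation,
invasive species) violate the optimistic assumptions listed above.

## Known limitations

* No reprojection; mixed-projection inputs are rejected, not fixed.
* Exact polygon edge-to-edge fragment distances are not implemented
  (documented proxy instead).
* The density/dispersal/MVP coefficients shipped are toy defaults, not
  fitted models.
* Fluctuation-based subcriteria, criteria A1/A3/A4, C2 and E, and the
  NT category are out of scope.
* Barriers to dispersal (rivers, roads) are ignored in the clumping
  step.
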