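# Methods

## The urban representation

The universal input is a flat table of polygonal urban elements in a
single projected, metre-unit CRS, with six attributes: `land_use` (the
category every parameter is keyed on), `land_use_verbose` (a finer label,
e.g. "Residence", used to identify homes), `floors` (0 for non-built),
`area` (m²), `flat_area` (the surface with slope < 5°, the area available
for conversion in scenarios) and `edible_area` (m² actually used to grow
edible plants; 0 outside urban agriculture). Geometry work never happens
in geographic coordinates: a degree-unit CRS is rejected at read time
rather than silently producing distances in degrees.

The per-land-use attribute table carries, for each of 14 urban-green land
uses, the green fraction `pGreen`, NO₂ sequestration capacity range
(`no2_seq1/2`, µg s⁻¹ m⁻²), food yield range (`food1/2`, kg m⁻² yr⁻¹),
SCS curve-number range (`CN1/2`) and four role flags. The flags are a
design choice of this package: `edible` marks the five urban-agriculture
solution types; `public` marks ground-level green open to anyone
(community gardens, arable land, permanent crops, grass, trees);
`private` marks domestic gardens (normal and edible private gardens —
"normal garden" is the source of private-garden conversions, so it is
treated as private rather than public); `harvest` (can store harvested
rainwater) covers the edible rows plus raised beds. All flags are
user-overridable through the CSV attribute-table format. Ranges always
satisfy lo ≤ hi and every parameter draw is uniform on its range —
deliberately uninformative within the stated bounds.

An indicator run over a city containing a land use with no table row is
an error that lists the unknown categories; silent zeros would hide data
mistakes. Because whole cities also contain non-green elements, a second
built-in table (`urban_attribute_table`) extends the green defaults with
impervious rows (Rooftop, Streets: pGreen 0, CN 98).

## Scenario generation

For each location class c ∈ {private gardens, ground plots, rooftops} the
builder takes the candidates (elements whose `land_use` is in the class's
source list), computes the target count n_c = round(p_c · |candidates|)
(ties away from zero) over *all* candidates, then filters candidates by
the class minimum area. If fewer eligible elements remain than n_c, all
are converted and a message "Only {eligible} … out of {n_c} assumed
satisfy the '{min_area_*}'" is recorded. Selection among eligible
elements is uniform without replacement — implemented as a prefix of a
random permutation, so nested proportions under a common seed convert
nested sets — except that commercial conversions (a `pCommercial` share
of ground and rooftop conversions) deterministically take the largest
eligible elements by the available-surface attribute: commercial
initiatives are assumed to secure the best spots. Community conversions
are then sampled from the remainder, which guarantees the smallest
commercial plot is at least as large as the largest community plot.
Private gardens always become edible private gardens regardless of
`pCommercial`.

Each converted element keeps its id, geometry, floors and areas; only
`land_use` changes and `edible_area` is set to u · available surface with
u drawn from the class's fraction range (defaults: gardens 0.02–0.30,
ground plots 0.52–0.75, rooftops 0.60–0.62; minimum areas 10/100/100 m²).
Element count and total area are therefore invariant. Each location class
draws from its own spawned random substream so that changing one class's
parameters never perturbs another's selection.

## Heat island

The diagnostic equation gives the canyon-minus-rural air-temperature
difference per raster cell: UHI_i = (2 − SVF_i − Fveg_i) · M with
M = (Q_ql·ΔT³/(C_air·P_air·U))^¼. The printed arrangement of the
meteorological factor is kept in one helper (`uhi_magnitude`) so an
alternative exponent arrangement can be swapped in for parity work. The
defaults (Q_ql = 6.11 W/m²/h, C_air = 1007 J kg⁻¹ K⁻¹, P_air = 1.14
kg/m³, ΔT = 10.8 °C, U = 2.77 m/s) describe a Western-Mediterranean
summer day and are used as plain numbers in the formula; their units are
not rescaled.

Fveg is rasterized from the polygons by cell-centre sampling: each cell
takes the `pGreen` of the polygon containing its centre (first polygon
wins on overlaps, 0 over no polygon), except that for edible land uses
the element-level ratio `edible_area/area` overrides the land-use
default. Cell-centre sampling keeps the operation deterministic and
resolution-consistent with the SVF raster; it ignores sub-cell coverage,
which is acceptable at the ~10 m cell sizes the indicator is used with.
Cells whose (2 − SVF − Fveg) is numerically negative are floored at 0 °C;
nodata SVF cells are excluded from the summary and from N in the mean.

## Runoff

The SCS curve-number model in metric form, S = 25400/CN − 254 (mm), with
CN drawn per element from [CN1, CN2]. The initial abstraction is
Ia = 0.2·S + min{Rh, Ws}/area: the harvested term is in litres while Ia
is in mm, so litres are divided by the element's surface (1 L/m² = 1 mm)
to keep the equation dimensionally consistent. Tank capacity Ws is a draw
from `tank_size` (default 0–45 L per m² of element surface, the reading
of "proportional to the surface of the element") times the element area.

Potential harvest Rh sums the storm depth times the areas of catchment
surfaces: non-edible elements within `harvest_dist` (default 10 m,
boundary-to-boundary) with strictly more floors than the harvester. Each
catchment surface credits only its *nearest* harvest-capable element, so
the same rain is never counted twice — a mass-conservation choice this
package makes deliberately where the behaviour was open.

City-scale runoff is the area-weighted mean of per-element Q (physically,
total runoff volume over total area); rainfall = P·ΣA/1000 (m³) is an
exact identity and is therefore invariant across scenarios on the same
footprint, a property the test suite checks exactly. Q ≤ P always, since
Q = (P−Ia)²/((P−Ia)+S) ≤ P−Ia.

## Accessibility and equity

Distances from each residence (full footprint, not centroid) to the
closest qualifying green are straight-line Euclidean minimum
boundary-to-boundary distances, 0 when the geometries touch. Qualifying
greens are the public-flagged land uses (or an explicit category list)
whose individual element area meets `min_area`; adjacent green polygons
are *not* dissolved before the threshold test. Defaults follow the WHO
recommendation (300 m to a public green area of at least 0.5 ha).

Green per capita in city mode is total green area over inhabitants. In
neighbourhood mode, elements straddling boundaries are apportioned by
intersection share (of the declared attribute area), each neighbourhood's
green is divided by its population, neighbourhoods under `min_inh`
inhabitants are dropped (industrial districts would otherwise dominate
the ratio), and the max/min ratio is returned. Green area is the full
polygon area, not pGreen-weighted: the metric counts green *areas*, not
vegetated fraction. With `private=True` the private-flagged land uses are
added to the green set, which can only increase every neighbourhood's
value.

## Monte-Carlo engine and the linear indicators

Jobs, volunteers and food production are linear in area with an uncertain
per-m² rate; 1,000 iterations propagate the uniform ranges and the
(α/2, 0.5, 1−α/2) empirical quantiles (linear interpolation, the same
type-7 convention as the six-number summaries) form the interval. Two
draw structures are exposed: jobs and volunteers draw *one* rate per
iteration (the coefficient is a property of the activity, applied
city-wide), while food production and NO₂ sequestration draw
independently per element (yield and capacity vary element to element).
NO₂ is reported as a single randomized total, not an interval, matching
its single-draw definition Σaᵢ·capᵢ/1000 — its per-seed value always lies
inside the analytic [Σa·lo, Σa·hi]/1000 bounds.

Purpose conventions: jobs count commercial solutions (commercial gardens,
hydroponic rooftops), volunteers count community solutions (community
gardens, rooftop gardens), edible private gardens count only toward food
production (personal use). With no element of the relevant purpose the
interval degenerates to zero rather than erroring — a city without
commercial gardens creates 0 jobs.

## Synthetic fixtures

The generator emulates the structure of a mid-sized-European-city
neighbourhood at block scale: a rectangular grid of square blocks
(default 10×10 blocks of 50 m, 10 m streets, ≈ 220 elements) assigned to
residential buildings (45%, 1–6 floors), vacant plots (15%), private
gardens (15%) and parks (15%) with the remainder paved, plus exactly one
pre-existing community garden so the base scenario already contains some
urban agriculture. Declared areas equal polygon areas exactly and
`flat_area = area`, so conservation identities are exact. Neighbourhood
layers are vertical slabs of the extent with given populations.

The companion SVF raster is a monotone transform of Gaussian-smoothed
built volume (floors rasterized at cell centres, ~30 m smoothing), scaled
to [0.15, 1] with 1 over open land: plausible spatial structure with the
right range and the right qualitative response (dense tall clusters give
low sky view), *not* a hemispheric visibility computation. Consequently
tests passing on these fixtures demonstrate the indicator algebra,
geometry handling and reproducibility — they do not validate the
photometric realism of SVF inputs, real urban morphology, or the
empirical accuracy of the default rate ranges on any particular city.

## Determinism and problem sizes

Every source of randomness flows from one master seed through named
substreams (`substream(seed, "jobs:s1")` etc., implemented with seed
sequences), so adding an indicator or scenario never perturbs another's
draws and the full report is byte-identical across runs with the same
seed. Default problem sizes — ~220-element city, 61×61 raster, 1,000
Monte-Carlo iterations — run the complete three-scenario report in well
under a second; they were chosen so the whole battery iterates quickly
while every eligibility class stays populated.

## Known limitations

Two-dimensional (plus floor counts) only: no vertical farming, no 3-D
shading. Only benefit indicators are provided; disservices (heavy-metal
uptake, nutrient runoff from rooftops, green gentrification) are out of
scope. Straight-line accessibility ignores the street network. The
scenario builder sites gardens randomly subject to size constraints; it
does not optimise placement. GeoPackage input is not supported — convert
to GeoJSON upstream; SVF rasters must be precomputed (e.g. with SAGA) or
synthesized.
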