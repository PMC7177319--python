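# Methods

## Scope and model

The package implements the computational side of a school-neighbourhood
built-environment (SN-BE) assessment: the audit sampling frame is derived
from a street network, streetscape audits are scored hierarchically, and
macro-scale metrics and validation statistics are computed per school
neighbourhood. The audited unit kinds are route sides and segment sides
(one per odd/even side of each street segment), crossings (one per
connecting road at each intersection with ≥ 3 legs) and cul-de-sacs
(recorded, never scored).

## Network buffer and sampling frame

The neighbourhood is a *network service area*: the set of points whose
shortest-path distance along road centrelines from the school address
point is at most a threshold (default 500 m, the conventional school
catchment for audit studies). Input centrelines are split at junctions —
any coordinate that ends a line or is shared by two lines — so segments
are maximal inter-junction pieces. Distances are computed with Dijkstra on
the undirected junction graph (one-way restrictions are ignored: the buffer
models pedestrians); each edge carries the covered interval(s) implied by
the endpoint distances, so frontier edges carry partial intervals. Coverage
is half-open: an edge touching the frontier at a single point (zero covered
measure) is not part of the frame.

Boundary protocol, applied to extracted segments:

* *Exclusion* — a partially covered segment with no residence on either
  side is dropped (and logged with its length).
* *Extension* — a segment covered from both ends, with ≥ 1 residence in
  each covered end and strictly more than half its length covered, is
  extended to a full audit unit (the bridged gap is logged). "Majority of
  the length" is read as coverage fraction > 0.5 strictly; an exact half
  does not extend. No upper bound is placed on the bridged gap length; the
  log carries it so users can impose one.

Side parity comes from house numbers (odd/even). When a side has no
address points both sides still exist — the audit requires two sides
regardless of addressing — with parity assigned by the identifier suffix
convention (`.O`/`.E` on the `school.street.segment` compound code).

Long segments are hard to audit consistently, so lengths are subdivided
into equal pieces of at most 200 m: ≤ 200 m whole, ≤ 400 m halves,
≤ 600 m thirds, and beyond that ⌈length/200⌉ equal pieces (a documented
extrapolation of the published rule, which stops at 0.6 km).

The school point snaps to the nearest edge within 50 m (configurable);
farther points raise a geocoding error. A disconnected origin component
smaller than the threshold yields a zone restricted to that component.

## Scoring

Items are ordinal integers with per-item recode maps (recoding lives in
the scheme configuration, not in code). Per audited unit, recoded member
items are summed into sub-scales and truncated at the sub-scale cap.
Negative-valence sub-scales are capped **then** negated — the cap bounds
the penalty magnitude. Section scores are signed sums of sub-scale values;
the overall grand score is the signed sum over all scored valence
sub-scales. School-level scores are unweighted means over audited units in
the requested side scope (odd / even / combined); a length-weighted
variant was considered and not adopted because school aggregation is
defined over audit units, but the worksheet output carries segment lengths
so users can weight externally. Route sub-section scores are computed
per street side and then averaged (per-unit-then-mean), not pooled over
items.

Crossing audits cannot be attributed to a street side, so the crossing
score of an intersection is the sum over its connecting-road audits and is
identical in every side scope. Because of this summation a formally
best-case school at a high-degree intersection could exceed the per-unit
scale maximum; the summary validates this softly (warning, not error) and
the scale maxima themselves are computed by dedicated scheme-level
functions.

A section with no audited unit in scope is reported missing and the grand
score flagged incomplete — never silently zero.

Cross-domain sub-scales (pedestrian infrastructure, pedestrian design,
bicycle facilities) are sums of school-level item averages over membership
lists drawn from several sections.

### The packaged default scheme

The published scoring system's item-by-item coding is distributed
separately from the scale description, so the packaged default scheme is a
constructed instrument that reproduces the published scale structure and
maxima exactly: positive section caps 50 (destinations & land use) + 40
(positive streetscape) + 15 (aesthetics & social) + 65 (segment) + 40
(crossing) = 210 grand points, and cross-domain maxima 27 / 22 / 11 as
sums of member-item maxima. Scheme validation is total: any scheme that
loads has every declared maximum verified by exhaustive best-case scoring,
every item in exactly one sub-scale, and complete recode maps. Users with
an exact coding document can encode it in the same YAML format.

## Macro metrics

The denominator area is a corridor polygon: the union of 95 m buffers
around the covered street intervals (shapely, 64 segments per quarter
circle, so circular caps are exact to ~1e-4 relative). One corridor area
serves both densities and the land-use clip; the radius is configurable.
Land-use mix is Shannon entropy of category area shares normalised by
ln k with k fixed at the 5 configured categories (residential, commercial,
industrial, tertiary campus, open space) regardless of how many are
present; pass `k` explicitly for the present-categories variant.
Walkability z-scores use the sample standard deviation (n − 1),
conventional for small school samples; a zero-variance component
contributes 0 for every school (warned). The index therefore sums to zero
across the sample by construction.

## Reliability and concordance

ICC is computed from the ANOVA mean squares of the targets × raters
matrix: one-way ICC(1), two-way random absolute agreement ICC(A,1) and
two-way consistency ICC(C,1), single-rater forms. The default is
ICC(A,1) — the conventional choice for two fixed-protocol auditors; the
model is selectable because reliability studies often do not name their
variant. 95 % CIs use the exact F-based closed forms (Satterthwaite
degrees of freedom for the agreement model); negative lower bounds —
common with few targets — are reported as computed, never truncated.
Rows with missing cells are dropped with a warning; zero between-target
variance yields ICC 0 with a warning rather than an undefined ratio.
Cicchetti bands classify the point estimate (boundaries inclusive:
≥ 0.75 excellent, ≥ 0.60 good, ≥ 0.40 fair, else poor).

For reliability matrices built from two-rater audit sets, targets are
street sides for the route/segment measures and intersections for the
crossing measure. School-level grand/cross-domain ICCs are not emitted at
the unit level because their unit of analysis is ambiguous in the source
protocol (a two-school co-audit gives n = 2 targets and degenerate CIs);
users can assemble any target matrix and call `icc` directly.

Concordance compares school-level odd-side and even-side scores per
measure: Pearson product–moment correlation by default, Spearman rank
correlation (average ranks for ties) for the two designated non-normal
measures (destinations & land use; bicycle facilities), two-sided
p-values via the t-approximation, no multiplicity correction (a Holm
adjustment can be applied downstream). The crossing measure is reported
combined-only. Correlations require ≥ 3 complete school pairs.

## Synthetic city generator

The generator emulates the study conditions the statistics were designed
for: 12 school neighbourhoods, gridded streets with ~100 m blocks (10 %
length jitter), ~1.5 residences per 100 m per street side, a
residential-dominated five-category land-use mosaic (60/15/5/5/15 %), and
modest item prevalence (mean item value 25 % of its maximum; 10 % for
crossing items, since pedestrian-crossing infrastructure is sparse at
typical intersections). The default 7×7 grid extends past the 500 m
buffer so the boundary protocol has genuine partial segments to act on.

Item values are generated from latent Gaussian pairs: per item and
segment, (z_odd, z_even) with correlation ρ (default 0.9) are mapped
through the standard normal CDF and the quantile function of a
Binomial(range, mean-level) to the item's integer range — exact latent
correlation control with ordinal output. Rater 2 equals rater 1 plus
rounded Gaussian noise clipped to the range, so the implied inter-rater
ICC is controlled by the noise sd. One seeded generator per run with
independent per-school sub-streams keeps outputs byte-identical for a
given seed.

What the generator does **not** emulate: real cartography (curved streets,
irregular blocks, cul-de-sacs as geometry), topography, spatial
autocorrelation of items along a street, overlapping school catchments
sharing audited units, and systematic rater bias. Passing tests therefore
demonstrate correctness of the computational pipeline under controlled
statistical structure, not field validity of any particular audit
instrument.

## Numerical choices and test sizes

* Junction matching rounds coordinates to 1e-6 (micrometres in projected
  metres); edge lengths are recomputed from the rounded polylines so graph
  weights are exactly consistent.
* Interval merging drops zero-length (< 1e-9 m) covered intervals.
* Service-area correctness is tested against a brute-force Floyd–Warshall
  + dense-sampling oracle on toy grids; ICC against an independent
  sums-of-squares oracle on the exhaustive sweep of all 4^6 3-target
  two-rater matrices with entries 0..3 (the smallest non-degenerate
  instance space that exercises every code path), plus a cross-check
  against an independent statistics library.
* Parameter-recovery checks run at the sizes the validation design calls
  for — 2000 replicate 12-point correlations and 500-target rating
  matrices — comparing replicate means to analytic values within ±0.02;
  averaging over replicates separates estimator bias from sampling noise.
* The end-to-end simulated study (12 schools, two raters) runs in a few
  seconds; the acceptance script's reported maxima are deterministic
  scheme properties.

## Known limitations

* The default scheme is a structural stand-in for the proprietary coding
  document: item names and ranges are plausible, maxima and hierarchy are
  exact, but item-level content is not the published instrument.
* Land-use proportions are measured by parcel area clipped to the corridor
  polygon; councils' "no-trim" polygon service areas may differ at the
  margin, so the corridor radius is exposed as a parameter.
* Overlapping neighbourhoods are not deduplicated by the simulator
  (schools are laid out disjointly); the scoring layer accepts shared unit
  references, so real overlapping data can be audited once and copied per
  school.
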