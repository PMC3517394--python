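# Methods

This note records the models, parameter choices, and numerical decisions
behind `blockscape`, in the spirit of a statistical package's methods
vignette. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Variable schema

The audit instrument is shipped as a flat CSV
(`src/blockscape/data/default_registry.csv`): 79 variables, each with a
domain, a provenance tag (literature, community, project leaders), an
applicability (parcel vs public space), and a value kind. Domain sizes are
housing damage 13, property disorder 14, territoriality 6, vacancy 3,
nuisances 26 (public space only), miscellaneous 17; parcel-applicable
variables total 53. Features assessed both privately and publicly (high
weeds, broken glass, litter, graffiti, discarded furniture / appliances /
tires) are two distinct variables, one per applicability, which keeps the
domains disjoint. Free-text "other condition/nuisance" entries count as
present when non-empty; property type, sub-type, front entry type, fence
material, and fenced area are categorical rather than presence/absence,
because they enumerate categories. Ordinal severity scales are deliberately
out of scope: presence/absence coding is what keeps multi-rater assessment
consistent.

## Queen contiguity and moving windows

Two blocks are adjacent when their boundaries share a segment or a vertex.
Real boundary files carry small misalignments, so contact is detected as
`distance(a, b) ≤ tolerance` with a default snap tolerance of 1e-6 map
units, exposed as a parameter; candidate pairs come from an STR-tree and
the builder is validated in tests against an all-pairs geometric oracle.
Coordinates must be planar; GeoJSON declaring a geographic CRS is rejected
unless explicitly overridden, because a tolerance in degrees is hazardous.
Multipart blocks are adjacent if any part touches any part. Invalid rings,
zero-area polygons, and duplicate ids are rejected rather than repaired.

Windows are graph-distance balls: order 0 the block, order 1 the PAC,
order 2 the SAC. Orders above 2 are rejected rather than extrapolated,
because the two community scales are the method's defined units. The SAC
equals both the BFS ball of radius 2 and the union of member PACs; both
characterizations are tested.

## Tenure classification

The address-match algorithm is a package design (the underlying
administrative practice specifies only intent: owner-occupied iff the situs
and owner mailing addresses match). Both addresses are canonicalized
(uppercase, punctuation stripped, directionals and street types mapped to
USPS-style abbreviations, unit designators split off); normalization is
idempotent by construction and property-tested. The score awards weights
for component agreement — street name 0.50, house number 0.20, directional
0.15, street type 0.15 — and a disagreement between two present house
numbers caps the score at 0.20, since different numbers on the same street
are different parcels. The decision threshold defaults to 0.85: high enough
that a name-or-number disagreement forces a renter call, low enough to
tolerate a missing component. All weights and the threshold are surfaced in
`MatchWeights` so the classification is auditable. Missing owner addresses
yield renter calls (score 0) under the binary scheme, or `unknown` in
strict mode; missing situs addresses are record-level errors, collected and
reported.

## Crime

Offense labels map to violent / property / vice / theft / vehicular by
exact case-insensitive lookup; unmapped labels are flagged `unclassified`,
and `total` counts every incident regardless of category. The packaged
mapping is illustrative — real deployments must supply the local label
scheme. Incidents are points assigned by point-in-polygon; a point on a
shared boundary goes to the lexicographically smallest block id (a
deterministic tie-break, shared with parcel assignment), and incidents
outside every block are returned separately so that the conservation
identity Σ_blocks total + |unassigned| = |incidents| always holds.

## Indices

Indices are raw counts, matching the summation construction of the source
methodology; because windowed counts grow mechanically with window size,
per-parcel rates (value / parcels in window) are emitted alongside, with
rates for zero-parcel windows reported as missing, never 0. The vacancy
index flags parcels that are unoccupied or demolished — of any property
type — plus vacant lots. The tenure index counts renter calls (a count
rather than a proportion, consistent with the other indices; the rate
column provides the proportion). Correlation matrices use Pearson by
default with Spearman as an option; a zero-variance index has its
correlations reported as NaN and flagged, not forced to 0. At least 3
blocks are required.

## Reliability

The one-way random-effects model treats raters as interchangeable draws
(each target may in principle be rated by different raters), which fits a
field team rotating across parcels:

    ICC(1)   = (MSB − MSW) / (MSB + (k−1)·MSW)
    ICC(1,k) = (MSB − MSW) / MSB

with confidence intervals from F = MSB/MSW on (n−1, n(k−1)) degrees of
freedom. The implementation is the ANOVA algebra directly; tests cross-check
point estimates and intervals against an independent implementation
(pingouin) and verify the Spearman–Brown identity on arbitrary inputs.
Degenerate (zero-variance) matrices are rejected: the ICC is undefined
there. Percent agreement is the mean over targets of pairwise rater
agreement. Long-format ratings are stacked across variables by
concatenating per-variable target rows (listwise deletion of incomplete
targets, reported); per-variable results are emitted alongside the pooled
row.

## Synthetic study areas

The generator emulates the study conditions of the field campaign the
package is built around: a 31×31 grid of square blocks (961, the nearest
square grid to the study's 944 blocks) with 18 parcels per block (~17.3k,
against a 17,242-parcel roster). Per-variable prevalences for the parcel
variables with printed observation counts are those counts divided by the
16,644 assessable parcels (e.g. boarded windows 0.135, peeling paint
0.209); unlisted binary variables default to 0.02. Public-space nuisance
points arrive at 36 per block with per-point probabilities proportional to
the printed nuisance frequencies, so the expected observation volume
(~33.5 per block) matches the published accounting of 31,652 observations.
The renter fraction defaults to 0.30 and the planted ICC to 0.70 (the
reported single-rater agreement level; with k=7 its Spearman–Brown average
is ≈0.94, close to but not exactly the reported 0.95 — the two printed
values are not exactly Spearman–Brown consistent, and we report what the
model computes). Crime rates per block (violent 0.5, property 1.5, theft
1.0, vehicular 0.7, vice 0.3) are package choices; no per-category volumes
were published.

An optional smooth latent field (Gaussian-filtered white noise on the block
grid, σ = 1.5 blocks, standardized) shifts prevalence logits, crime
log-rates, and the renter logit by index-specific loadings. The default
loadings (property disorder 1.0, nuisances 1.0, housing damage 0.6,
territoriality/vacancy/crime 0.35, tenure −0.3) plant the qualitative
correlation structure of the published matrix: disorder and nuisances
co-vary most strongly, tenure runs opposite. Because the top published
correlations differ by only a few hundredths, a single small realization
can transpose the ranking; the planted-factor checks therefore either use
enough blocks (≥100) or average over seeds.

What the generator does **not** emulate: real urban morphology (blocks are
squares), spatially clustered parcels within blocks, rater drift, address
typos (owner addresses are either verbatim copies or entirely unrelated),
and geocoding error. Tests passing on synthetic data therefore demonstrate
algorithmic correctness and statistical calibration under the stated
model, not robustness to messy administrative data.

All randomness flows from one integer seed through spawned child
generators (one per data stream), so identical configs are byte-identical
and streams are independently reproducible.

## Test and acceptance problem sizes

The suite exercises small cities (4×4 to 10×10 blocks, 6–25 parcels per
block) and 20-seed replicate sets, chosen so the whole suite runs in well
under a minute while leaving binomial noise small relative to the asserted
tolerances. The smoothing check uses a 0.02 absolute tolerance on the
coefficient-of-variation decrease across scales, covering CV estimation
noise at 36 blocks. ICC recovery uses 200 replicates at n=200, k=7 with a
±0.05 band on the mean estimate. `scripts/acceptance.py` uses a 10×10-block
city (1,800 parcels) for the pipeline-level quantities and 200 replicates
at the field protocol's 50×7 for reliability; at these sizes the script
completes in seconds.

## Known limitations

- The offense mapping and the address-match weights are package defaults,
  not reconstructions of the original administrative algorithms, which were
  never published.
- Sidewalk segments are modeled as data (polylines with broken/obstructed
  flags in the schema's source material) but no sidewalk index is defined.
- Orders beyond the SAC, alternative contiguity rules (rook, k-nearest,
  distance bands), kappa-type reliability statistics, and two-way ICC
  variants are out of scope.
- Published study-area-specific results that depend on the restricted field
  data (per-variable prevalences, the numeric correlation matrix, the
  944-block geography) are context, not reproduction targets.
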