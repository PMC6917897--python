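# Methods

This note documents the models, numerical conventions and design choices
behind `brainsig`, and what the synthetic studies do and do not establish
about behaviour on real atlas data.

## The synthetic study

The generator emulates the data regime of a point-sampled donor
transcriptome paired with a meta-analytic term map.

**Volume and term map.** An isotropic voxel grid (default 30×36×30 voxels
of 2 mm) with a diagonal affine, split along the third axis into a
subcortical (lower) and cortical (upper) compartment. A term map places
`n_foci` spherical foci (default 4, radius 10 mm, alternating between
compartments) whose peak z is uniform on [2, 8] and decays linearly to the
sphere boundary, so a voxel is strictly positive exactly when it lies
inside a focus; 5% of background voxels receive scattered negative z. The
downstream code never assumes this affine shape — co-registration goes
through the general affine inverse.

**Samples.** Each donor contributes `n` samples per compartment (default
100) on distinct voxel centers, stratified so that at least half fall in
positive-z voxels; region labels partition each compartment into 2×2×2
spatial blocks shared across donors, which gives the differential-stability
score a common region frame.

**Expression.** For a planted gene with target correlation ρ (default 0.8)
the gene-level value at sample *s* is `sign·ρ·z̃(s) + √(1−ρ²)·ε` with
`ε ~ N(0, noise_sd)` and z̃ the map z standardized over that
donor-compartment's samples — linear-Gaussian by design so the population
per-donor Pearson correlation equals ρ analytically, which is what the
parameter-recovery tests exploit. Non-planted genes carry a donor-shared
random linear gradient of amplitude 0.4 plus noise: spatially structured
(so probe selection has signal to work with on null genes too) but
uncorrelated with the map in expectation. Gene-specific compartment
baseline offsets (SD 2) are added and must be removed by the
per-compartment z-scoring. Each gene expands to `probes_per_gene` probes
(default 3): one low-noise winner (probe SD 0.05, the intended
differential-stability choice) and high-noise decoys (SD 2.0), of which a
fraction (default 0.4) are "dark" — above background in only ~30% of
samples, so the background filter removes them.

**Gene sets, pools, evidence.** Five of 50 sets (default) are planted:
~80% of their members come from one (function, sign) planted pool, sizes
15–30; every planted gene is guaranteed membership in at least one planted
set of its sign. Null sets are uniform draws of size 15–50. Known-gene
pools are the planted genes topped up with random non-planted genes to 80;
evidence flags (strong/weak per function, mutually exclusive) are drawn
only for pool members, with planted genes preferentially strong. Because a
function's planted genes are excluded from the other function's pool, the
synthetic evidence is cleaner than a real literature review; precision
scores on synthetic candidate lists therefore sit near 1 rather than in
the 0.7–0.95 range a curated review produces.

**Determinism.** A single master seed spawns per-stage child generators
through fixed `SeedSequence` spawn keys, so identical configurations give
byte-identical outputs and individual stages can be re-run in isolation.

## Preprocessing conventions

* Background filter: a probe is kept iff its above-background fraction is
  ≥ 0.5 — the exact-50% boundary is retained — computed per donor over all
  of that donor's samples, and the probe must pass in **every** donor so
  all donors share one probe universe.
* Differential stability: expression averaged within region per donor; DS
  is the mean over donor pairs of the Pearson correlation between the two
  region-mean vectors, restricted to regions sampled by both; pairs sharing
  fewer than two regions are skipped; probes with no valid pair are
  unscored and genes with no scorable probe are dropped globally, keeping a
  single gene universe for the ranked list.
* Probe selection: highest DS wins; ties break to the lexicographically
  smallest probe id (deterministic across platforms).
* z-scoring: sample standard deviation (n−1), per donor per compartment;
  zero-variance genes become all-zero and are flagged; a compartment with a
  single sample is an error rather than silently skipped.

## Co-registration

Samples snap to the nearest voxel by rounding the affine-inverse image
half-away-from-zero (platform-stable). Masking is strict: z = 0 voxels are
excluded along with negative ones. Smoothing averages, per donor and gene,
over all retained samples within 6 mm Euclidean distance including the
sample itself — a row-stochastic operator on the sparse point set rather
than a voxel-grid convolution, which is deterministic and
resolution-independent; and it is applied **after** masking, so excluded
voxels contribute nothing. Both choices are stated because the original
order of operations is ambiguous in tools of this kind; radius 0 reduces
to the identity, which the tests use as an anchor. A donor-compartment
retaining zero samples is excluded from correlation and logged.

## Correlation and ranking

Per gene and donor: OLS slope/intercept of expression on z and the Pearson
r, requiring ≥ 3 points; zero variance on either side flags the fit
invalid. The random-effects summary is deliberately the *unweighted*
arithmetic mean of valid per-donor r — no variance weighting and no Fisher
transform (available via `fisher=True` but off by default). Genes with
fewer than two valid donors are excluded: a one-donor mean is not a
random-effects statistic. Ranking is descending by mean r with
lexicographic tie-breaks, so the list is a deterministic function of the
correlations.

## Enrichment

Weighted running-sum enrichment with exponent p = 1 by default
(configurable; p = 0 recovers the classical two-sample KS statistic, which
is verified against a brute-force oracle). ES is the signed extreme of the
running sum; an exact tie between the positive and negative extreme
resolves to the positive one. The null is gene-tag permutation — ES of
random same-size sets drawn without replacement — because a pre-ranked
list has no phenotype labels to permute; 1,000 permutations by default,
cached per set size. The batched null evaluates the running sum only at
hit positions (between hits it falls linearly), which the tests verify
against per-set scoring. NES divides ES by the mean same-signed null ES;
the nominal p is the same-signed null tail fraction, floored at
1/(n_perm+1) when empty; FDR q is the sign-stratified ratio of null to
observed NES tail fractions, capped at 1. Set sizes outside [15, 500]
after intersection with the ranked universe are skipped.

Leading edges are members at or before the running-sum peak (positive ES)
or at or after the trough (negative ES). Candidate lists count leading-edge
memberships across significant same-sign sets and order by count, then
|mean r| (most extreme first — inferred from the observed orderings of
published candidate tables), then gene id, truncated to 10. An analysis
with no surviving sets emits no candidate list; downstream validation
skips it gracefully.

Overlap percentages are 100·shared/union rounded half-up to one decimal
(via `decimal.Decimal`, avoiding binary-float rounding surprises); the
over-representation test is the upper-tail hypergeometric probability with
Benjamini–Hochberg adjustment across sets. In place of interactive network
visualisation the package exports plain node/edge tables with Jaccard
overlap edges.

## Validation statistics

* Chance probability: the product form Π_{i=0..N−1} (K−i)/(M−i) — the
  probability that *all* N candidate hits land in the pool — which equals
  C(K,N)/C(M,N) exactly and is cross-checked against binomial coefficients.
  This all-draws-in-pool reading (rather than a hypergeometric tail over
  the 10 candidates) is the model that reproduces every reference value.
* Precision: strong evidence 1 point, weak ½; target score =
  target/(target+control); a zero denominator yields an undefined, flagged
  result, never 0/0.
* Correlation differences: target r minus control r per gene of the
  significant sets, negated for negative-sign lists so the expected
  direction is positive.
* Bootstrap: 10,000 iterations subsampling without replacement (a
  `replace=True` option exists) to the smallest significant-set gene count
  of the function; percentiles use linear interpolation between order
  statistics; "significant" means the central 95% interval strictly
  excludes zero — an interval touching zero is not significant.

## Problem sizes and what the tests show

The standard synthetic study (4 donors, 2,000 genes × 3 probes, 100
samples per donor per compartment, ρ = 0.8, 5 planted sets of 50) runs the
full pipeline in seconds and is the condition under which planted-set
recovery (≥ 90%) and candidate precision (≥ 8/10 planted) are asserted;
null calibration uses 500 random sets against a no-signal study. These
sizes exercise every code path at comfortable statistical margins.

Passing them shows the machinery is correct and calibrated under the
generator's assumptions — linear-Gaussian expression, isotropic affine,
idealised background flags, clean evidence. It does not show robustness to
what real atlases add: spatial autocorrelation in the *null* genes'
relation to the map (no autocorrelation-preserving null maps here),
donor-specific batch structure beyond z-scoring, anatomically realistic
geometry, hemispheric asymmetry, or probe-to-gene annotation error. Those
are explicit non-goals.

## Known limitations

* The FDR procedure reconstructs the published pre-ranked method's
  sign-stratified NES-ratio; minor numerical differences from specific
  releases of the original tool are expected.
* The chance model assumes all 10 candidates drawn from one universe; it
  is undefined for lists longer than 10 by construction.
* Region labels in the generator are spatial blocks, not anatomical
  parcels; differential stability behaves correctly but its absolute
  values are not comparable to atlas-derived ones.
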