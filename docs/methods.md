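# Methods

This note documents the statistical procedures `salamet` implements, the
choices made where the underlying study design left them open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Pipeline order and cleaning rules

The pipeline begins at an OTU read-count table; sequence processing (read
QC, clustering, taxonomy assignment) is upstream and out of scope. Two
cleaning steps precede every dietary metric:

1. **Relative-read filtering.** An OTU is retained iff its within-sample
   relative read count reaches the threshold in at least one sample
   (OTU-level survival). The default threshold is 0.01% — common
   metabarcoding practice, not a value taken from any particular study —
   and it is a mandatory, report-logged configuration field. An alternative
   per-cell interpretation (zero individual sub-threshold cells) is
   available behind `mode="per_cell"` because the literature uses both
   readings; the per-OTU default matches the way surviving-OTU counts are
   usually reported.
2. **Host-DNA exclusion.** OTUs flagged as the sampled animal itself are
   removed *before* any denominator is formed, so RRA and prey-specific
   abundance are proportions among prey reads only. Samples emptied by this
   step are flagged (`empty_after_host_removal`) and excluded from the
   sample count S of all three diet metrics, since the metrics are
   undefined on empty samples; the exclusion count is carried on the
   profile output.

Collapse to analysis taxa or families sums reads over OTUs sharing a label;
unknown families pool into `Unclassified/Other`. Total reads are conserved.

## Diet metrics and the Costello diagram

%FOO, %RRA and %P<sub>i</sub> are computed exactly as defined in the
README. Their invariance structure is asserted by tests: FOO and RRA are
invariant to per-sample sequencing depth (rescaling any sample's reads),
prey-specific abundance is not — it intentionally weights samples by their
read totals within the occurrence set.

The Costello diagram itself is qualitative; no numeric region boundaries
exist in the method's literature. The labels emitted
(specialized/generalized, dominant/rare, BPC-/WPC-leaning) are therefore
pure functions of the point and two configurable split percentages
(default 50/50), and outputs always carry the raw coordinates alongside the
labels so readers can re-draw the regions. Percentages are written to TSV
at 1 decimal place; full precision is kept internally.

## Jacobs' selectivity

D = (r − p)/(r + p − 2rp) with r the family's RRA share (an `use="foo"`
switch exists for sensitivity analysis; FOO shares are renormalized to sum
to one first). Families detected in the diet but outside the survey's
identification scope keep p = 0 rather than being dropped — that is how the
exact D = +1 boundary arises in practice — and survey-only families get the
−1 boundary. The denominator vanishes only at (r, p) = (0, 0), where D is
reported as NaN (undefined), and at (1, 1), where the indifference limit
D = 0 is returned. Name matching is exact-string with an optional
user-supplied synonym map; fish and benthic references are normalized and
screened separately via the reference table's `group` column.

## Habitat-shape circularity

Circularity = 100 × contour area / minimum-enclosing-circle area, in
[0, 100], scale invariant, equal to 100 only in the circle limit
(square: 200/π ≈ 63.66%). Components:

- **Area**: absolute shoelace sum; orientation independent.
- **Minimum enclosing circle**: Welzl's randomized incremental algorithm
  with a seeded shuffle (deterministic output), exact to floating point;
  every run is certified by re-checking that all points lie within the
  returned radius at 1e−9 relative tolerance. The test suite compares it
  against an O(n⁴) brute-force enumeration of all pair- and triple-defined
  circles on 200 random instances.
- **Validity**: self-intersecting outlines are rejected (shapely validity
  check) because the contour area would be ill-defined; outlines whose
  convex hull carries (numerically) no area are reported as degenerate with
  circularity 0 instead of raising.
- **Raster masks** are traced along pixel edges (a single foreground pixel
  yields its unit-cell square; marching-squares-style subpixel contours
  were rejected because they cut pixel corners and bias small shapes). The
  mask must contain exactly one foreground component under the configured
  4- or 8-connectivity; at checkerboard pinch vertices the walk pinches
  corners apart (4-connectivity) or carries across the diagonal
  (8-connectivity). A rasterized disk of radius 100 px recovers the vector
  circularity within ~2%.

Circularity values computed from digitized site drawings in any particular
survey depend on the drawings themselves; the module reproduces the
statistic, not any specific published mean.

## Habitat screen

- **Correlations**: Pearson r with two-sided p from
  t = r√(n−2)/√(1−r²), pairwise-complete observations (sites that dried up
  lack chemistry), per-pair n reported, pairs with n < 3 skipped with a
  warning. Bonferroni correction multiplies only the environment-vs-egg-sac
  row by the family size (default 9 — the nine environmental variables
  tested against the response), capped at 1; the 45 off-response pairs are
  exploratory context and left uncorrected.
- **Power**: Fisher-z approximation,
  power = Φ(ζ − z₁₋α/₂) + Φ(−ζ − z₁₋α/₂) with ζ = atanh(|r|)·√(n−3).
  Exact at r = 0 (returns α); an approximation elsewhere and labelled as
  such.
- **VIF**: 1/(1 − R²) by least-squares regression of each predictor on the
  rest (with intercept); exact collinearity returns `inf` rather than
  raising, because duplicate measures (DO mg/L vs DO %) are a finding, not
  an input error. Cross-checked against statsmodels in the tests.
- **PCA**: SVD of the column-centred standardized table (correlation-matrix
  PCA when input is z-scored). Variance percentages sum to 100 over all
  components; each component's sign is fixed so its largest-magnitude
  loading is positive, making outputs reproducible across platforms.
  Cross-checked against scikit-learn.
- **Descriptive summaries**: mean, SE = sd/√n, CI = mean ∓ z·SE with
  z = 1.96 (normal multiplier, not a t quantile — the convention that
  published mean ± SE tables of this design reproduce at 2 d.p.).
- **`infer_sample_size`** inverts a printed (r, p) pair through the
  two-sided t transform by root finding; applied to a correlation table's
  response row it checks whether all pairs are consistent with a single n.
  The consistency check documents the inferred n; it does not assert it as
  any survey's true sample size.

## Community comparison

One-way PERMANOVA on squared dissimilarities (Anderson's partition;
formulas in the module docstring), free shuffling of group labels (single
factor design), seeded generator recorded in the result, and the add-one
p-value convention p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), which bounds p
below by 1/(n_perm+1). Occurrence matrices are binarized before Jaccard;
read tables are row-normalized to proportions before Bray–Curtis (a
`braycurtis_raw` mode skips normalization for sensitivity analysis). Under
the null, the permutation p-value is uniform and the type-I error at
α = 0.05 sits in [0.03, 0.07] over 1000 simulations with 199 permutations —
asserted by the test suite at exactly those sizes to keep runtime near a
couple of minutes; production runs default to 9999 permutations.

Rarefaction uses the exact hypergeometric expectation
E[S_d] = Σᵢ [1 − C(N−Nᵢ, d)/C(N, d)] with log-gamma binomials, so depths in
the 10⁵–10⁶ read range are numerically safe; the curve is monotone and
concave in depth, and matches Monte-Carlo subsampling at 10⁵ replicates
within 0.01 taxa in the tests.

## Synthetic-data generator

The generator provides inputs with the structure the analyses assume, at
the scale of the motivating study design:

- **Diet tables**: 18 samples per habitat group by default; per-taxon
  occurrence drawn Bernoulli with group-specific probability; conditional
  on the occurring set, read counts multinomial from Dirichlet-perturbed
  mean shares with concentration = dispersion × shares (one overdispersion
  knob, default 50); ~150,000 reads per sample (the order of magnitude of
  post-QC read totals per sample in surveys of this kind; per-sample depth
  distributions are rarely published, so this is an order-of-magnitude
  choice); a reserved `HOST_SELF` OTU takes a binomial share of reads
  (default 0.5 in expectation — typical for unblocked fecal metabarcoding)
  so host exclusion is testable. Every occurring taxon is guaranteed one
  read so planted occurrence probabilities equal expected FOO exactly; the
  default 12-family roster's occurrence contrasts echo the restored-vs-
  alternative patterns the package is designed to measure.
- **Site tables**: multivariate normal via eigenfactorization of a planted
  correlation matrix (validated symmetric PSD; eigenvalues ≥ −1e−8
  tolerated and clipped), scaled to configured means/SDs. The default
  10-variable matrix is the published site-correlation structure of the
  motivating study (with the egg-sac/conductivity sign taken from the text,
  −0.211, where table and text disagreed), which is positive definite and
  can be planted verbatim; the default n_sites = 125 is the sample size
  that the published (r, p) pairs jointly imply under the t transform.
  Egg-sac counts are a rounded, zero-truncated latent Gaussian; with the
  default mean 40 and SD 12 the truncation mass is ~4e−4 and rounding adds
  variance 1/12, so attenuation of the planted Pearson structure is below
  1e−3 — negligible against the ±3/√n recovery tolerance the tests use.
  Means/SDs are otherwise round, field-plausible values; they affect scale
  only, not the planted correlations.
- **Outlines**: all shapes are radial polygons r(θ) with multiplicative
  radial noise clipped away from zero, so generated outlines are
  star-shaped and provably simple at any noise level.

What the generator does **not** emulate: sequencing error, chimeras, PCR
and primer bias, tag jumping (the phenomena the relative-read filter exists
for), taxonomy misassignment, spatial autocorrelation among sites, and
non-Gaussian chemistry marginals. Passing recovery tests therefore show
that the estimators are correct under the assumed sampling model, not that
the cleaning rules would rescue real contaminated libraries.

## Numerical conventions and degenerate inputs

- Seeds: every stochastic component (simulators, PERMANOVA, the enclosing
  circle's shuffle) takes an explicit seed; the CLI derives independent
  child seeds from one master seed via `SeedSequence` and records them in
  the run report.
- Ties and zeros: FOO uses strict n > 0 occurrence; Jaccard of two empty
  vectors is 0 by convention (logged in the docstring); Bray–Curtis of two
  all-zero vectors is an error; prey-specific abundance of a never-occurring
  taxon is NaN, never 0.
- Test problem sizes (200 enclosing-circle instances at n ≤ 60, 1000 null
  PERMANOVA simulations at 199 permutations, n = 2000–5000 for correlation
  recovery, 10⁵ Monte-Carlo subsampling replicates) were chosen as the
  smallest sizes at which the stated tolerances are comfortably inside
  sampling noise.

## Known limitations

- PERMANOVA is one-way only; no PERMDISP companion test, so location and
  dispersion effects are confounded in principle.
- The Fisher-z power formula is approximate for small n.
- Pairwise-complete correlation matrices need not be positive definite.
- Exact-string family matching will silently treat unsynonymized spellings
  as distinct families; supply a synonym map when mixing taxonomies.
- The mask tracer ignores interior holes (outer boundary only), consistent
  with treating a site outline as its wetted perimeter.
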