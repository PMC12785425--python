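# Methods

## Study design being modeled

A chronic restraint stress (CRS) time course in mice: six durations
(0, 7, 14, 21, 28, 35 days), two sexes, eight animals per cell (96
total), weekly behavioral assessment, and terminal quantification of 11
prefrontal-cortex markers — eight proteins by immunoblot (GAD67, VGLUT1,
PSD95, SYN1, GPHN, GLT1, GFAP, GS) and three transcripts by qPCR (SST,
PV, VIP). Markers are grouped into three functional compartments:
GABAergic (GAD67, SST, PV, VIP), synaptic (VGLUT1, PSD95, SYN1, GPHN)
and astroglial (GLT1, GFAP, GS).

## Normalization and data hygiene

Immunoblot values are band intensity over total protein, qPCR values are
`2^-(Ct_target − geomean(Ct_ref1..3))`; both are rescaled so the mean of
the unstressed (CRS0) group is 100 ("percent of control"). The control
reference pools both sexes; sex-stratified normalization is available as
an option. Note one subtlety: because the reference aggregation is the
geometric mean of *cycle* values, adding a constant to all Ct values of
a record is not an exact no-op unless the three reference Cts coincide.

Outliers are flagged per (marker, group) with a two-sided Grubbs test at
α = 0.05, at most one removal per cell — the single-extreme-sample test
appropriate for n ≈ 16 groups. The choice of test is this package's; any
documented small-sample outlier rule could be substituted. Flagged
values become missing, and missing values are imputed with the
group × sex mean so that imputation cannot leak a sex effect into the
sex-split network analyses. Zero-variance groups flag nothing.

## Behavioral scoring

- **Coat state**: sum of seven body-part scores (head, neck, dorsal and
  ventral coat, tail, fore- and hindpaws), each 0 / 0.5 / 1; range 0–7,
  ordinal. Correlations involving coat state therefore use Spearman.
- **Weight gain**: percent change from the animal's week-0 weight.
- **Sucrose preference**: sucrose as percent of total fluid; a week with
  zero total intake yields a missing value rather than a division error.
- **Residual avoidance (RA)**: from overnight PhenoTyper traces binned
  into clock-aligned, half-open hour bins. A 1-h light challenge starts
  at 11 p.m.; the statistic is the animal's zone time summed over the
  five bins following challenge end (midnight–5 a.m.),
  `RA_i = s · 100 · (T_i − T̄_c)/T̄_c` with the same-week, same-sex
  control mean `T̄_c` and sign `s = +1` (shelter) / `−1` (food zone), so
  more shelter time and less food-zone time both read as avoidance and
  controls average to zero identically. The published formula for RA
  lives in a cited protocol paper rather than in the study itself; this
  signed-percent-deviation form satisfies every stated constraint
  (controls at 0, stressed animals positive, percent units) and is
  flagged as a reconstruction — it may not be numerically identical to
  the original. Traces missing any post-window bin yield a missing RA.
- **Z-emotionality**: for each of the five measures, a z-score against
  the sex-matched control mean and SD, multiplied by a deficit-aligned
  direction (+1 coat state, +1 RA-SZ, +1 RA-FZ, −1 sucrose preference,
  −1 weight gain — stress *blunts* weight gain), then averaged over the
  measures available for that animal. A measure with zero control SD is
  dropped for that sex with a warning (this happens legitimately at
  week 0, where weight gain is identically zero).

## Association analyses

Marker–marker correlations over all 55 unique pairs form one BH-FDR
family; marker–behavior correlations are reported with raw p plus a
family q for transparency. Pairs with fewer than three complete cases or
a constant member produce missing coefficients, not errors. PCA operates
on columns standardized to mean 0, SD 1; components are oriented so each
component's largest-magnitude loading is positive, making output
deterministic; variance explained sums to 100% over all components, and
each marker's correlation with the first three component scores is
reported.

## Co-expression networks and module preservation

Per group × sex cell (≥ 4 animals, complete data): Pearson correlation
matrix `r`, Fisher transform `z = atanh(r)` (|r| clamped at 1 − 1e−12),
and weighted adjacency |r| with zero diagonal.

**Module detection** is average-linkage hierarchical clustering of the
signed dissimilarity `d = 1 − r`, cut at `cut_fraction ×` (maximum merge
height), default 0.75; branches with ≥ 3 markers become modules
(numbered in order of first marker), smaller branches stay unassigned.
An 11-node dendrogram does not benefit from adaptive tree cutting; a
static cut keeps the partition a deterministic function of `r`. The cut
fraction was set by analyzing the planted-block recovery problem: the
top (between-module) merges of a correlation dendrogram concentrate near
`d ≈ 1` with sampling scatter, while within-module merges sit near
`1 − r_within`, so the cut must sit well below the top merges; recovery
of planted blocks is insensitive to the exact value across 0.5–0.8, and
0.75 is the midpoint of that plateau. Cutting at 0.99 of the maximum
height — superficially analogous to dynamic tree-cut defaults — lands
between the top merges often enough to fuse distinct modules.

**Preservation** of module `M` (from the shorter-duration group of a
pair) in the other group's partition is
`max_N |M ∩ N| / |M|` over that partition's modules `N`; ties prefer the
larger `N`, then the lower label; unassigned markers never count.

**Permutation test**: the two cells' animals are pooled and reassigned
at random to pseudo-cells of the original sizes; networks and partitions
are rebuilt from scratch each draw (10,000 by default). The null
hypothesis — identical modules — is exchangeability of animals between
the groups. Because a pseudo-partition need not have the observed module
count, observed and null per-module preservations are aligned as order
statistics: the k-th smallest observed value is compared against the
k-th smallest value of each draw, padding draws with fewer modules with
1.0 (a missing pseudo-module is no evidence of low preservation). The
identical functional is applied to the observed and to every permuted
split, so each per-module empirical p is valid under exchangeability.
Empirical p-values use the add-one estimator
`(#{null ≤ obs} + 1)/(n_perm + 1)`, one-sided toward low preservation,
never returning 0 (floor ≈ 1e−4 at 10,000 permutations). Module
p-values combine per pair by Fisher's method (`−2Σ ln p` against
chi-square with 2k df); the 15 pair-level p-values per sex are then
BH-corrected. The published description is ambiguous about whether BH
precedes Fisher; per-pair meta-analysis first matches the per-pair
(p, q) reporting convention and is the order implemented. A pair whose
first group has no modules reports p = 1 with a log entry. Degenerate
draws (a constant marker in a pseudo-cell) are redrawn and counted;
with continuous data they essentially never occur.

## Hubness

Kleinberg's hub score of an undirected weighted graph is the principal
eigenvector of its adjacency; for symmetric non-negative matrices hub
and authority scores coincide and the vector is non-negative
(Perron–Frobenius). It is computed by power iteration on the diagonally
shifted adjacency (shift = max row sum; eigenvectors unchanged,
convergence guaranteed), to elementwise tolerance 1e−10, then
max-normalized to 1. Centrality uses the full 11-marker |r| graph — no
module restriction or edge threshold, since the hub score should reflect
the whole correlation field; only the *degree* metric applies an
inclusion threshold (default |r| ≥ 0.3) so that degree is not trivially
n − 1. Hub-score changes of each CRS group versus same-sex CRS0 use the
same pooled-permutation scheme with two-sided add-one empirical
p-values. Compartment-level inference combines a compartment's marker
p-values by unweighted Stouffer meta-analysis with signs from the
observed differences: `z_i = d_i · Φ⁻¹(1 − p_i/2)`,
`Z = Σz_i/√k`, combined p `= 2(1 − Φ(|Z|))`, direction `sign(Z)`.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
under which every downstream guarantee is demonstrated.

- **Expression**: per animal, `100 + effect(marker, group) +
  sex_offset(marker for males) + ε`, with `ε` multivariate Gaussian
  (SD 15 percent units — a typical immunoblot CV), correlation 0.5
  within a compartment and 0.1 between (positive-definiteness checked),
  truncated at 0. After missingness (default rate 0.002, matching the
  2 missing cells of 96 × 11 in the modeled study) each marker is
  rescaled so the non-missing control mean is exactly 100, mirroring how
  percent-of-control normalization behaves on real quantifications. The
  default effect profile is graded decline with round magnitudes:
  VGLUT1 early (−15 to −25%), SYN1/PSD95 late, GAD67 mid-course, GFAP
  mild; males run higher on GFAP, SYN1, GPHN, PV, VIP. These are
  fixtures shaped like the phenomenon, not estimates of any dataset.
- **Behavior**: weekly records over weeks 0–5 with staggered stress
  onset so every group completes its duration at week 5. Shelter-time
  shifts (6–15 min per post-challenge bin) are programmed for every
  stressed group from its first stressed week; the sucrose-preference
  deficit (−12 points) only at 35 days; coat state and blunted weight
  gain grade with duration. Zone occupancy per hour bin is drawn from a
  Dirichlet split of the 60 minutes (shelter/food/elsewhere), and the
  stress shift is added only in the five post-challenge bins.
- **Determinism**: one seed, split into independent substreams for
  expression, missingness, behavior and traces; identical configurations
  give byte-identical CSVs.

What the generator does *not* emulate: litter, cage and estrous effects,
attrition, assay batch structure, non-Gaussian quantification error, and
any duration-dependent change in the *correlation* structure (group
effects move means only). Consequently, passing calibration tests shows
the permutation machinery is valid under exchangeability — it does not
certify power against every real-data alternative. The directional
checks show the mean-shift profile is detectable: pooled permutation of
two cells with different means inflates pseudo-network coherence, which
lowers the preservation p-value distribution relative to a no-effect
profile (a paired comparison across seeds, since effect and null cohorts
of the same seed share noise draws).

## Numerical and procedural choices

- Empirical p-values: add-one (never 0), floor `1/(n_perm + 1)`.
- Fisher/Stouffer refuse p = 0 unless an explicit floor is supplied.
- |r| = 1 is clamped to 1 − 1e−12 before `atanh`, with a log entry.
- Module labels, PCA signs and permutation streams are all deterministic
  functions of (input, seed); pipeline reruns are byte-identical.
- Pipeline stage seeds derive from one global seed via `SeedSequence`
  spawning, so stages are independently reproducible.
- Problem sizes used by the test suite: calibration over 200 null
  cohorts at 500 permutations; planted-module recovery over 100
  replicates at n = 200; oracle equivalence over 1,000 random instances
  per primitive; directionality over 50 paired cohorts at 500
  permutations. These sizes give the binomial/rank tests involved
  comfortable resolution while keeping the default suite quick.

## Known limitations

- The RA formula is a reconstruction (see above); a switch to the
  original formula is a one-function change.
- With 8 animals per cell, single-pair network comparisons have low
  power; the permutation framework is honest about this (wide nulls),
  but users should not expect single-cohort significance.
- The static dendrogram cut, the full-network hub score, the
  Fisher-then-BH ordering and the order-statistic null alignment are
  documented package choices where the published description is silent
  or ambiguous; all are configurable or isolated behind one function.
- Grubbs assumes approximate normality within a group; for heavy-tailed
  quantification error it over-flags.
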