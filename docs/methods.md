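# Methods

This note documents the models, conventions and design choices behind
`growthshape`, in the order the pipeline applies them.

## Z-scoring and reference tables

Measurements are converted to z-scores with the LMS method:
`z = ((x/M)^L − 1)/(L·S)` for L ≠ 0 and `z = ln(x/M)/S` for L = 0, where
L (Box–Cox power), M (median, in kg, cm or kg/m²) and S (coefficient of
variation) are tabulated per standard segment, sex, measure and age.
Both the forward and inverse transforms are implemented with
`expm1`/`log1p` so they remain mutually inverse to machine precision
even for |L| arbitrarily close to the L = 0 switch (taken at
|L| < 1e-12). L, M and S are interpolated linearly in age between
bracketing rows; queries outside a table's range are errors, not
extrapolations.

Four standard segments are used, mirroring common practice of scoring
newborns on a GA-keyed standard and older children on under-5 / over-5
references:

| segment | age axis | used at |
|---|---|---|
| `newborn_by_ga` | GA at birth (days) | birth |
| `infant_postnatal` | postnatal days (corrected for preterm) | 3-month visit |
| `under5` | postnatal days ≤ 1826 | 12 m – 4 y visits |
| `over5` | postnatal days > 1826 | 6 y, 11 y visits |

The 5-year boundary is 1826 days (⌊5 × 365.25⌋); a visit exactly on the
boundary stays on the under-5 reference. At the 3-month visit a preterm
child is scored at the GA-corrected age (postmenstrual-equivalent
convention, configurable via `preterm_m3_corrected`); corrected ages are
clamped at 0 days so they remain on the table. Under the GA-corrected
analytical approaches the corrected age is used at every post-birth
visit. Missing measurements, and a missing GA at birth, produce missing
z-scores rather than errors.

The shipped reference tables are synthetic: saturating-exponential-plus-
linear median curves for weight and height (BMI medians derived from the
two), plausible constant L and S per measure, small sex offsets, and the
schema of real WHO/INTERGROWTH-style tables so that published
coefficients can be dropped in through the same CSV format. They are
stand-ins, not published coefficients.

## Plausibility cleaning

A z value is flagged when it lies outside per-index hard bounds
(WAZ ∈ [−6, 5], HAZ ∈ [−6, 6], BMIZ ∈ [−5, 5]) or when the jump to or
from the nearest non-missing neighbouring visit exceeds `max_step`
(default 4 z-units). Cleaning then sets a flagged value to missing when

* it violates a hard bound (unconditional), or
* it deviates by more than `max_step` from **both** its nearest
  preceding and nearest following non-missing neighbours; a value at the
  observed edge of the series (one neighbour only) is removed when it
  deviates from that neighbour, but only after no two-sided outlier
  remains — the interior context is resolved first, so a spike adjacent
  to the edge is removed rather than the edge point it distorted.

Removal is iterated to a fixpoint (removing a spike can create a new
large step), which makes cleaning idempotent. Values that were flagged
at any stage but never removed are reported as retained warnings. This
deterministic rule replaces the manual inspection step a human analyst
would apply; it is configurable and every action is written to the
cleaning report.

## Exclusion cascade

Children are removed in a fixed order, each counted once at its first
triggering rule: (1) missing, conflicting or implausible GA (outside
22–45 weeks, i.e. 154–315 days); (2) missing or implausible birth
weight/length (defaults 0.3–6.5 kg, 25–60 cm); (3) exactly one attended
post-birth visit; (4) fewer than `min_obs` (default 3, birth included)
non-missing observations in *any* of HAZ/WAZ/BMIZ. The report reconciles
exactly (input = retained + Σ reasons) and the cascade is stable on its
own output. Rule 4 intentionally reads "either index": a child with
seven weights but two heights is excluded.

## Age scales and baseline centering

GA-corrected age subtracts the missed gestation (280 − GA days) from
every postnatal age of a preterm child; term children are unchanged
unless `apply_to_term` is requested. Near birth the corrected age can be
negative; consumers decide (the z-scoring step clamps at 0, the
clustering step uses the corrected value as-is).

Baseline centering replaces every value of a per-index series by
`v − factor·v_birth` with factor 1.002. All between-visit differences
are preserved exactly (up to float rounding), so only the trajectory's
level changes. The near-unit factor is kept as the canonical default —
it leaves a residual of `(1 − factor)·v_birth` (e.g. 0.004 for a birth z
of −2) rather than an exact zero; this implementation tolerates exact
zeros, so `factor=1.0` is a valid configuration and gives exact
shift-invariance (a constant added to a whole trajectory is then
invisible after centering; with 1.002 a 0.2 %-of-shift residual
remains). Children whose birth z is missing for an index are excluded
from that index's centered analyses, with their ids reported — never
silently dropped.

## Shape distance

The generalized discrete Fréchet distance is computed by dynamic
programming over monotone couplings of the two observed vertex
sequences (each step advances one or both sequences). Point cost is
`sqrt((λ·Δage_months)² + Δz²)`; aggregation is `max` (classical Fréchet,
default) or `sum` (DTW-like; not a metric). Missing visits are simply
absent from the sequence — no imputation. The DP is exact on vertices
and is verified in the tests against exhaustive enumeration of every
monotone coupling for all pairs of trajectories with up to 6 points.

λ defaults to 0.1 z-units per month and is deliberately exposed:
results depend on it. Two limits anchor the interpretation: at λ large
enough that `λ·(smallest age gap)` exceeds the z-range, the distance on
equal-age trajectories equals the Chebyshev distance between z-vectors
(time realignment becomes prohibitively expensive); at λ = 0 the
coupling may realign time freely, so the distance is bounded above by —
and on shape-shifted trajectories strictly below — the Chebyshev
distance. That inequality, not equality, is what makes the metric
shape-respecting.

## Clustering

Lloyd-style k-means: assignment by Fréchet distance to each centroid,
centroid update as the LOWESS mean pattern of the cluster's pooled
(age, z) points (tricube-weighted local linear regression, span 0.5, one
robustifying iteration), evaluated on a fixed 40-point age grid — 24
points in [0, 24] months and 16 up to 132 months, denser early where
growth is fastest. Iteration stops when no label changes (`max_iter`
100). An emptied cluster is reseeded with the trajectory farthest from
its current centroid.

Initialization defaults to k-means++-style D² sampling with 5 restarts,
keeping the run with the lowest total within-cluster distance. Uniform
random initialization (available as `init="random"`) is unreliable when
class frequencies are unbalanced — with a ¼/½/¼ structure the chance
that three uniform draws hit three different classes is only ~19 % — and
the deterministic farthest-point variant (`init="maximin"`) can seed an
outlier instead of the middle band. Everything is reproducible from a
single integer seed (restart sub-seeds are spawned from it).

Cluster-count selection computes three indices per k on the Fréchet
distance matrix: mean silhouette width, a Calinski–Harabasz analogue
built from centroid distances, and total within-cluster distance (elbow
by largest curvature). The recommendation is the majority vote, ties to
the smaller k — and it is advisory: an analyst may prefer, say, k = 3
over an index-optimal 2 to keep an interpretable intermediate pattern.
This is a deliberate subset of the large battery of indices available
elsewhere, chosen to cover the three main index families
(separation-vs-cohesion, variance-ratio, scree).

With k = 3, clusters are named High / Middle / Low by the descending
time-average of their mean pattern; exact level ties are broken by the
pattern's mean slope (larger = higher). For other k, rank names C1…Ck
are used. Centered approaches cluster on centered series but report mean
patterns and features on the un-transformed z-scores, so "High" always
refers to attained growth and results remain comparable across
approaches.

## Features and statistics

Per child and index, an OLS line over the observed (age-months, z)
points yields the intercept (z at age 0), slope (z/month) and tempo —
the area under the fitted line from 0 to the child's last observed age
T, divided by T, which for a line is `intercept + slope·T/2`. The
integration endpoint is the child's own T on the age scale of the active
approach; "average growth per month" then refers to the observed life
span. Children with fewer than two observed points are skipped and
logged.

Between-pattern feature differences use the Kruskal–Wallis omnibus test
(tie-corrected, scipy) followed by Dunn's pairwise z-tests on the pooled
ranks with tie correction; pairwise p-values are Holm-adjusted by
default (Bonferroni and unadjusted available). Groups with fewer than
two members are skipped and flagged.

Malnutrition classification uses strict cutoffs: stunting HAZ < −2,
underweight WAZ < −2, wasting BMIZ < −2, overweight BMIZ > 2, obesity
BMIZ > 3, with overweight/obesity reported as mutually exclusive tiers
(2 < z ≤ 3 vs z > 3). Birth is excluded from prevalence tables (newborn
size is not a malnutrition phenotype on the postnatal references).
Category-by-pattern contingencies are tested with the uncorrected
Pearson chi-squared; any expected cell below 5 raises a warning.
Cross-approach mobility aligns patterns by name (High↔High), counts
off-diagonal movers, and reports the adjusted Rand index; when the two
labelings use different name sets only the ARI is reported.

## Synthetic cohort generator

The generator emulates a birth cohort followed at birth, 3, 12, 24 and
48 months and 6 and 11 years (visit means 3.0, 11.9, 23.9, 49.5, 81.6,
132.0 months with jitter SDs 0.1, 0.2, 0.4, 1.7, 3.6, 3.6). Each child
draws sex (48.2 % female), preterm status (11.7 %), GA (term:
N(276.5, 14) days truncated to [259, 315] — the upper bound keeps every
generated GA inside the cascade's own 45-week plausibility envelope and
the newborn table; preterm: N(246, 14) truncated to [154, 258]) and a
latent class with probabilities ¼/½/¼. The latent z-trajectory is

    z(t) = b0 + b1·t + A·exp(−t/τ) + ε,   τ = 8 months,

with per-class intercepts b0 ~ N(0.64, 0.30), N(−0.55, 0.30),
N(−1.85, 0.35) for High/Middle/Low, slopes b1 ~ N(0.004, 0.0015),
N(0.0005, 0.0015), N(−0.003, 0.0015) z/month, catch-up amplitudes
A = +0.4 / 0 / −0.3, visit noise ε ~ N(0, 0.25), and child-level
HAZ/WAZ offsets N(0, 0.15). The class intercept means follow the kind
of High/Low feature levels reported for real cohorts; the generative
SDs are smaller than the within-pattern spreads such studies tabulate
because those are post-assignment (truncated) spreads — with these
defaults the latent classes are recoverable end-to-end at ARI ≈ 0.8–0.9
(n = 600), which is the intended regime: distinct but not trivially
separated. The decaying-exponential component creates the heterogeneous
first-two-years growth that baseline centering is designed to reveal.
`GeneratorConfig.well_separated()` provides the 10-σ-separation variant
used for exact-recovery checks. Measurements are obtained by inverting
the LMS reference at the same ages and standards the scorer uses, so
re-scoring reproduces the latent z-values exactly when noise is the only
randomness; a truth table (class, GA, per-visit true z) ships beside
every generated cohort.

What the generator does **not** emulate: secular trends, twinning,
mortality and loss-to-follow-up correlated with growth, socioeconomic
structure, measurement rounding, or skewed real-world GA distributions.
Passing tests therefore demonstrate correctness of the pipeline's
machinery and its behaviour under a known latent structure — not that
any particular real cohort has three classes.

The engineered exclusion cohort contains exactly 4231 children of whom
41 have missing/discordant GA, 47 implausible birth anthropometry, 105 a
single follow-up and 93 fewer than three observations in some index
(disjoint groups in cascade order; the last group keeps three weights
but only the birth length, exercising the "either index" rule), leaving
3945 valid — a fixed-point check of the whole cascade.

## Numerical and interface conventions

* Ages are stored in days and converted to months as days / (365.25/12).
* One month of age mismatch ≡ 0.1 z by default (λ); aggregation,
  centering factor, span, k, bounds and min-obs are all config keys
  (YAML/JSON, unknown keys rejected).
* Per-visit z maps hold NaN for missing; trajectories enter distances
  only through their non-missing points.
* All randomness flows from integer seeds; pipeline outputs include a
  manifest with package version, seed, config hash and input SHA-256s,
  so a tampered config or input is detectable and identical inputs
  reproduce identical label files.
* Problem sizes in the test-suite and acceptance script (600-child
  recovery cohorts over 5 seeds, 1000-draw calibration loops, 4231-child
  cascade fixture) were chosen as the smallest sizes at which the
  checked statistics are stable.

## Known limitations

* The discrete Fréchet distance is exact on observed vertices but does
  not interpolate between visits; with ≤ 7 visits per child this is the
  appropriate granularity, for dense series a continuous variant would
  differ.
* `sum` aggregation violates the triangle inequality; silhouette and CH
  values computed on it are heuristics.
* LOWESS centroids are not Fréchet barycenters, so the k-means objective
  is not guaranteed monotone in theory (it is in practice on separated
  data, and the assignment step always is).
* Dunn's test uses the normal approximation; very small groups warrant
  exact methods.
* Exact reproduction of any specific published cohort's memberships is
  not claimable: the distance weight λ, aggregation, initialization and
  convergence details of other implementations are typically
  unreported.
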