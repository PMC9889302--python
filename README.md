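# growthshape

Shape-based clustering of child growth trajectories for cohort
epidemiology: anthropometric z-scoring against age- and sex-specific
growth references, gestational-age (GA) correction of the age scale,
baseline (birth-size) centering, and k-means clustering with a
generalized discrete Fréchet distance, followed by characterization of
the resulting growth patterns.

## The problem

Cohort studies summarise child growth as average trajectories, which can
hide subgroups of children whose growth *progresses* differently —
early faltering followed by catch-up, steady decline, and so on.
Clustering individual trajectories exposes that heterogeneity, but three
methodological choices matter:

1. **Distance.** Point-wise distances (Euclidean at each visit) confound
   shape with level and cannot handle missing visits or irregular
   schedules. The discrete Fréchet distance couples two vertex sequences
   monotonically and scores either the worst aligned pair (classical,
   `max`) or the summed cost (`sum`), with point cost
   `d(p,q) = sqrt((λ·Δage)² + Δz²)` mixing the time and z axes through a
   weight λ (default 0.1 z-units per month).
2. **Baseline centering.** Subtracting `1.002 × z_birth` from every value
   of a trajectory moves its intercept to ≈ 0 while preserving all
   between-visit differences, so clusters reflect the *shape* of growth
   rather than size at birth.
3. **GA correction.** For preterm children (GA < 37 weeks = 259 days),
   `corrected age = postnatal age − (280 − GA at birth)` compares each
   child with reference children of the same postmenstrual maturity.

Crossing GA correction with centering gives four analytical approaches;
run over three indices (height-, weight-, and BMI-for-age z-scores:
HAZ, WAZ, BMIZ) they produce 12 clustering result sets whose mutual
agreement (adjusted Rand index, mobility tables) is itself informative.

Z-scores use the LMS method: a reference distribution at each age is
summarised by a Box–Cox power L, median M and coefficient of variation
S, and `z = ((x/M)^L − 1)/(L·S)` (the log form when L = 0). Implausible
values are flagged (|z| outside per-index bounds, or between-visit jumps
above 4 SD) and removed when the neighbouring visits confirm them as
outliers. A four-rule exclusion cascade (missing/discordant GA,
implausible birth anthropometry, a single follow-up, fewer than 3
observations in any index) selects the analysable cohort.

Because individual-level cohort data of this kind are typically
restricted, the package ships a first-class synthetic-cohort generator
(`growthshape.simulate`) with a known three-class latent structure
(High/Middle/Low ≈ ¼/½/¼), ~12 % preterm births, jittered visit
schedules, visit-level missingness and synthetic LMS reference tables,
so the full pipeline is testable end to end.

## Worked example

```bash
growthshape simulate --n 300 --seed 1 --out example
growthshape cluster --cohort example/cohort.csv --lms example/lms_reference.csv \
    --index HAZ --seed 1 --out example/haz_plain
growthshape cluster --cohort example/cohort.csv --lms example/lms_reference.csv \
    --index HAZ --seed 1 --center --out example/haz_centered
growthshape mobility \
    --labels-a example/haz_plain/HAZ_ncorr_ncent/labels.csv \
    --labels-b example/haz_centered/HAZ_ncorr_cent/labels.csv
```

prints

```
HAZ_ncorr_ncent: {'Middle': 0.493, 'High': 0.31, 'Low': 0.197}
HAZ_ncorr_cent: {'Low': 0.347, 'High': 0.33, 'Middle': 0.323}
b       High  Low  Middle
a                        
High      33   29      31
Low       23   15      21
Middle    43   60      45
ARI = 0.0039; movers = 207 (69.0%)
```

Reading this: without centering, HAZ clusters split the 300 children
roughly half/quarter/quarter by attained level. With baseline centering
the same children regroup by growth *shape* — 69 % change pattern and
the agreement between the two partitions is essentially at chance
(ARI ≈ 0), i.e. centering asks a genuinely different question of the
data. Each output directory also contains per-child features
(`features.csv`: OLS intercept in z, slope in z/month, and tempo — the
time-average of the fitted line), smoothed mean patterns on a 40-point
age grid, malnutrition-by-pattern chi-squared tables, and a provenance
manifest (seed, config and input hashes).

The same steps are available as library calls (`run_pipeline`,
`kmeans_shape`, `frechet_distance`, …); `growthshape run-all` executes
all 12 approach × index result sets in one go.

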