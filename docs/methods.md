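# Methods

`regalforage` implements a complete analysis stack for asking whether male
and female individuals of a protandrous flower-visiting insect use
different nectar plants, how much of any difference phenology explains, and
whether nectar chemistry separates female- from male-associated plants.
This note records the models, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Data model

The universal input is a long-format table of feeding observations:
`year`, `ordinal_day` (January 1 = 1), `sex` (`F`/`M`), `plant_species`,
and an optional positive `count` defaulting to 1 — the survey records
individual nectaring events, and the optional count column only serves
pre-aggregated inputs.  Duplicated rows are legal (two butterflies on the
same plant on the same day) and are flagged by validation but never
removed.  Species labels are whitespace-normalized and compared
case-insensitively, with the first-seen spelling kept as canonical; two
decades of hand-entered field data motivate the tolerance.  A `dialect`
mapping on the reader absorbs arbitrary column headers.

## Ambiguous congeneric assignment

Some thistle visits are recorded only as `"Cirsium spp."` although two
species with well-separated phenologies occur (*Cirsium pumilum* early,
*C. discolor* late).  With ordinal day as the single feature, any
maximum-margin linear classifier reduces to a day threshold, so the
assignment stage is a 1-D rule fitted on the unambiguous records pooled
across years: for separable classes the boundary is the midpoint of the
closest pair of training days (the exact hard-margin solution, verified
against a linear SVM in the tests); for overlapping classes it is the
threshold minimizing weighted training error, ties broken by proximity to
the midpoint of the class means.  A record exactly on the boundary goes to
the class with the greater training weight within ±7 days (deterministic,
locally frequency-weighted).  Assignment conserves record counts, touches
only ambiguous records, and stamps them with an `assigned` provenance flag.

## Phenological overlap

Weeks are fixed 7-day bins anchored at ordinal day 1 (days 1–7 = week 1);
calendar/ISO weeks would make results depend on the year and locale.  The
overlap window of a year runs from the first week in which females reach at
least 25% of observations through the last week in which they are at most
75%.  A second convention — ending at the first week in which females
*exceed* 75% — is available via `rule="methods"`; the two coincide whenever
the female share rises monotonically through the season.  Windows are
inclusive at day resolution on both ends.  Years whose window contains
fewer than `min_days = 4` distinct survey days are excluded outright
(exclusion is a value with a reason, not an error): a window of 1–3
observation days cannot support a within-year comparison.

Median foraging dates use the weighted lower-median convention
(deterministic integer day).  The post-hoc regression of yearly
dissimilarity on the absolute female–male median-date gap is ordinary least
squares; a constant response or constant gap returns slope 0, R² 0 by
convention rather than a numerical artifact.

## Diversity

Per sex-year assemblages are visit-count vectors over plant species.
Richness counts species with positive counts; Shannon entropy uses the
natural log with 0·ln 0 = 0, and the effective species number (ESN, Hill
number of order 1) is `exp(H)` — the number of equally visited species with
the same entropy.  ESN is scale-invariant and bounded above by richness
with equality exactly at uniform visitation.  No rarefaction is applied:
each sex-year uses all of its records.

The sex contrast is a linear mixed model `metric ~ sex + (1 | year)` fitted
by REML (statsmodels `MixedLM`), with year as a random intercept absorbing
the pairing of male and female values within a year.  When the between-year
variance estimate collapses to zero the model is singular and the code
falls back — with a logged notice — to the paired t-test, which is the
identical inference in that case.  statsmodels reports large-sample
(z-based) p-values and no Satterthwaite degrees of freedom; the result
carries the residual df (`n_years − 1` under the paired structure) as an
explicitly approximate convention.  Residual autocorrelation is screened
with the sample ACF at lags 1..min(15, n−2) and the Durbin–Watson statistic
`Σ(e_t − e_{t−1})² / Σe_t²` on per-year mean residuals ordered by year.

## Dissimilarity and the Patefield null

For each year with both sexes present, visits form a 2×S table.  The
abundance-based Morisita–Horn dissimilarity

    d_mh(x, y) = 1 − 2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²) · X · Y]

is 0 for identical relative composition and 1 for disjoint assemblages,
symmetric, invariant to proportional rescaling of either vector, and
clamped to [0, 1] against floating-point rounding.  The
information-theoretic "Horn overlap" variant is deliberately not used; the
implementation is cross-checked against `vegan::vegdist(method = "horn")`.

The null model keeps every row and column margin fixed and randomizes
which sex each visit is paired with.  Sampling uses sequential conditional
multivariate-hypergeometric row fills (numpy's generator), which draws
exactly from the generalized hypergeometric distribution over tables —
the distribution a Patefield swap chain converges to, and the same law as
brute-force shuffling of individual visit labels.  Tests verify this
against exact enumeration of label shuffles on all small margins and
against R's `r2dtable`.  Each year is scored by the percentile interval
(linear-interpolation quantiles at (1±level)/2) of 1000 null d_mh values;
a normal-approximation interval is available via `ci_method="sd"`.
Classification is `above` / `within` / `below`.  A single-species year is
degenerate: observed and null d_mh are identically 0, the interval is
[0, 0] and the year is `within`.  A master seed spawns one stream per year
(`default_rng([seed, tag, year])`), so per-year results do not depend on
the order in which years are processed and reruns are bit-identical.

## Sex–plant association

Visits are pooled across years into one 2×S table (optionally restricted to
the most visited species; the pipeline reports both the full table and the
six most visited).  Pearson's chi-squared test of independence is computed
without continuity correction — the table is 2×S with large counts — and
expected cells below 5 are listed in a warning while the test still runs.
Cell residuals `(O − E)/√E` satisfy `chi2 = Σ residuals²` exactly.  A plant
is labeled female-associated when its female-row residual exceeds +2,
male-associated below −2, else neutral; 2 approximates a standard-normal
criterion and, on data with the structure simulated here, produces the
2-male / 4-female split of the six focal species.

## Nectar chemistry

Concentrations are screened per species × compound: a value more than
`k = 4` sample standard deviations (ddof = 1, candidate included in its own
group) from the group mean is removed and reported.  Note an arithmetic
consequence of self-inclusion: with n values the largest attainable |z| is
(n−1)/√n, so a 13-replicate group can never produce |z| > 3.33 — the 4·SD
rule only ever fires on groups large enough or spikes extreme enough in
combination.  Groups with fewer than three values are never screened.

Family totals (total carbohydrates, total amino acids) are computed per
biological replicate as the sum over all detected compounds of the class —
configurable via a compound→class map — and compounds undetected in more
than half of all samples are excluded a priori (the phenylalanine rule).

Each compound is modeled with species-specific means and species-specific
residual variances; nectar traits are strongly heteroscedastic across
species, and a pooled-variance model would miscalibrate the contrast.  The
planned contrast weights +1/n_F on each female-associated species mean and
−1/n_M on each male-associated one, so the estimate is the difference of
group averages of species means — invariant to adding a constant,
antisymmetric under swapping the group labels.  Its variance is the
Welch–Satterthwaite sum `Σ w_i² s_i²/r_i` with approximated denominator df
`var² / Σ(w_i² s_i²/r_i)²/(r_i−1)`; the pooled-residual df `Σ(r_i−1)` is
reported alongside for comparison rather than forced.  With one species per
group the contrast reduces exactly to Welch's t-test (used as a test
oracle).  `F = (L/SE)²` on (1, df); species with a single replicate are
excluded with a warning.  Bonferroni families divide the family alpha by
the family size: 0.05/5 = 0.01 for the five carbohydrates, 0.05/4 = 0.0125
for the four amino acids.

## Synthetic data

The generator defines the study conditions every test runs under.
Defaults: 21 years; weekly survey days over ordinal days 153–281; Gaussian
flight curves truncated to the season, male peak day 180 with spread 14,
female peak 194 (two-week protandry) with spread 18 (longer female
activity, consistent with reproductive diapause; additional right-skew is
deliberately off so the null configuration stays exactly calibratable);
Poisson daily counts scaled to about 155 visits per sex-year (the long-term
average of the emulated survey).  Eight plant species bloom on trapezoidal
availability curves (linear ramps to a plateau — the minimal shape that
creates seasonal turnover and near-forbidden links): early milkweeds
preferred by males, mid/late thistles, knapweed and beebalm preferred by
females, plus two minor generalists.  A visit's plant is multinomial in
availability(day) × preference(sex).  Fifteen percent of the two thistles'
records are masked to `"Cirsium spp."`.

Interannual variation in timing is explicit: each year draws a shared
timing shift (SD 5 days, both sexes) and independent per-sex shifts (SD 3
days).  Without the per-sex component every synthetic year would have an
identical median-date gap and the gap regression would be degenerate; with
it, year-to-year variation in dissimilarity partly tracks the gap, the
mechanism the overlap analysis is designed to probe.  The
`SeasonConfig.symmetric()` preset — used for calibration — gives both sexes
one flight curve (shared jitter only), equal preferences and no masking, so
visit sex labels are exchangeable and the null test's `above` rate must hit
the nominal one-tail 2.5%.

Every realized count is returned as truth (per year × sex × plant, plus the
true species of each masked record), and totals are conserved exactly
between truth and the emitted records.  Identical seeds give byte-identical
output; per-year streams are independent of year ordering.

What the generator does *not* emulate: observer effort variation and
multiple transects, within-week survey-day jitter, overdispersed
(non-Poisson) counts, floral abundance fluctuation beyond the fixed bloom
curves, and any correlation between nectar chemistry and visitation.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under a clean generative model, not robustness to
every field artifact.

The nectar generator draws log-normal concentrations parameterized so the
natural-scale mean and SD match the per-species profile (SD 0 yields
constant replicates), 13 replicates per species with 8 for *Cirsium
discolor*, and supports an additive group shift on the female-associated
species for recovery tests.  The default profiles are synthetic: chosen so
female-associated species run sugar- and amino-acid-richer with strongly
species-specific variances, qualitatively like real panels; they carry no
empirical claim.

## Pipeline and determinism

`run_pipeline` executes: validation → ambiguous assignment (when needed) →
full-season dissimilarity, diversity and association → overlap-window
detection and restriction → the same analyses on the overlap dataset
(plus association over only the years whose overlap dissimilarity is
`above`) → the median-gap regression → nectar screening and contrasts.
Reports are TSV tables plus one JSON bundle; they contain configuration,
seed and package version but no wall-clock content or output paths, so the
same inputs and seed give byte-identical files anywhere.  Stage failures
abort with the stage name attached.

## Problem sizes

Defaults everywhere follow the emulated study (21 years, ~155 visits per
sex-year, 1000 null replicates, 13/8 nectar replicates).  The calibration
ensembles in the acceptance checks use 200–400 simulated years at 1000
nulls each and 1e5 sampler draws for the exactness checks; these sizes put
the Monte-Carlo error well inside the asserted bands while the whole suite
stays interactive.

## Known limitations

- Mixed-model p-values are large-sample; with few paired years they are
  slightly anti-conservative relative to a t reference.
- The Satterthwaite df for the nectar contrast is an approximation; with
  very small replicate counts per species (< 5) its calibration degrades.
- The chi-squared association labels use a fixed ±2 residual threshold; no
  multiplicity control is applied across species labels.
- The overlap-window rule operates at week resolution; day-resolution
  windows would need a different (unspecified) smoothing convention.
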