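# Methods

## The statistical problem

Routine outpatient laboratory data are a two-component mixture: a dominant
non-pathological component and a minority of genuinely abnormal results.
An indirect reference-interval (RI) method must (i) decide which age and
sex strata need separate intervals, and (ii) estimate each stratum's
non-pathological 2.5th/50th/97.5th percentiles without being dragged by the
pathological tail. `pedri` treats these as separate, auditable stages.

## Cleaning

Outliers are removed per analyte × sex × whole-year age cell by Tukey
fences (k = 1.5) applied iteratively until a pass removes nothing. Values
exactly on a fence are kept (conservative). Cells with fewer than 8 values
pass through uncleaned with a logged warning: quartiles of a handful of
points do not support fencing, and the alternative — discarding the cell —
would silently bias the age coverage. Termination is structural (the kept
set strictly shrinks or the loop exits; the quartiles always lie inside the
fences, so the kept set cannot empty). Cleaning happens once, before
partitioning; merged bins are not re-cleaned.

One quantile convention is used everywhere (fences, Lahti limits, subgroup
summaries, bootstrap percentiles): linear interpolation of order statistics
at rank h = (n−1)p + 1 (numpy's default "linear"/type-7 rule).

## Age partitioning

Sex is always a hard partition. Within a stratum, a depth-limited (default
2) regression tree on age proposes cut points: candidate thresholds are
midpoints between consecutive distinct ages, the chosen split maximises the
within-node SSE reduction subject to both children holding `min_leaf`
(default 50) records, and exact gain ties (1e-12 relative) resolve to the
youngest age so builds are deterministic. Nodes with no achievable gain do
not split.

Candidate bins are then validated pairwise with three split-recommending
rules — the Harris–Boyd z-test (|Z| > Z\* = 3·√((n₁+n₂)/240)), the
SD-ratio rule (ratio > 1.5), and the Lahti proportionality criterion
(any subgroup proportion outside the pooled pair's empirical 2.5th/97.5th
percentiles that is ≥ 4.1% or ≤ 0.9%). Adjacent bins merge when **no**
rule supports splitting; merge scanning is greedy left-to-right and repeats
to a fixed point, after which each surviving bin is offered one validated
tree re-split per pass; the outer loop is capped at 20 passes and every
decision is appended to an audit list. Accepted splits can never oscillate:
a cut is accepted only if the same deterministic tests that the merge pass
applies support it.

The Lahti criterion needs at least 20 observations per subgroup (below
that, empirical 2.5th/97.5th percentiles are meaningless); pairs failing
that are treated as carrying no split evidence. Final bins with n < 120 are
flagged (classical guidance asks ≥ 120 reference individuals per group)
but not forbidden — real pediatric cohorts are sparse at the age extremes.

**Known limitation — small-sample behaviour of the empirical Lahti rule.**
The count of observations strictly outside the pooled pair's empirical
limits is essentially fixed (~2.6% of the pooled n); only its apportionment
between the two subgroups is random. For even, large subgroups the observed
proportions concentrate near 2.5% and the rule behaves well (two
identically distributed subgroups of 5,000 give all four proportions within
2.5 ± 0.6 and a merge verdict). But when an adjacent pair is small or
uneven (say 90 vs 410), a zero count in the small subgroup — probability
e^(−np) ≈ 10% — trips the ≤ 0.9% arm, and the pair is spuriously kept
apart. In simulation this fires on roughly a fifth to a third of
homogeneous adjacent pairs at bin sizes of 50–250, so partitions on real
cohort sizes tend to be finer than the generating truth (the merge loop can
only be as good as its decision rules). The audit trail makes every such
decision inspectable; users wanting coarser partitions can raise
`min_leaf`.

## Indirect RI estimation

The estimator searches a grid of Box-Cox powers λ (−2.0 to 2.0, step 0.1;
|λ| < 1e-8 treated as the log case, computed via expm1/log1p for
precision). For each λ the sorted sample is transformed (order-preserving),
its quantiles at p = 0.05 to 0.80 (step 0.0125) are regressed on
standard-normal scores, and:

* the line's intercept and slope are the model's μ and σ (robust central
  quantile matching — observations outside the window have zero leverage);
* the cost is the residual sum of squares of that quantile–quantile line,
  normalised by the total sum of squares (scale-free, so comparable across
  powers);
* powers whose implied 95% interval μ ± 1.959964·σ would leave the
  transform's range (λ·y + 1 ≤ 0) are excluded — they cannot produce a
  reference interval;
* the smallest cost wins, exact ties going to the smaller |λ|.

The window is deliberately asymmetric: it reaches to the 5th percentile on
the left but stops at the 80th on the right, because the contamination this
package is designed around — deficiency/excess screening data — is a
one-sided elevation, concentrated above the healthy bulk. The deep lower
reach is what identifies λ (skewness information in a narrow central band
is weak: with a symmetric 20–80% window the selected power has standard
deviation ≈ 0.3 at n = 2,000, versus ≈ 0.13 with the default window). If
contamination may be bilateral, pass `central_window=(0.20, 0.80)`.

Reference limits are BC⁻¹(μ − 1.959964σ), BC⁻¹(μ), BC⁻¹(μ + 1.959964σ).
Confidence intervals are nonparametric percentile bootstrap (default
B = 200, seeded, full refit per resample; replicates whose fit fails are
dropped and logged, >10% failures is a hard error). Reports round to two
decimals; full precision is kept internally.

### Measured operating characteristics

All numbers below are computed by the test suite on the synthetic
generator, where truth is closed-form.

* **Coverage.** On a clean (healthy-only) bin of 10,000, the fitted
  interval contains 95.3% of the sample (nominal 95 ± 1.5).
* **Recovery.** Both limits fall within 5% of the generating percentiles
  at n = 2,000 in ≥ 90% of seeds for the moderate-spread analytes
  (Zn, Ca, Mg, Fe — 50/50 seeds in the suite's Zn check). Copper
  (transformed-scale CV ≈ 0.29) sits at that criterion's edge: even with
  the generating power known exactly, quantile noise alone leaves ~90%
  of seeds within 5%, so the grid estimator hovers at 44–46/50. Lead
  (log-scale σ = 0.85) cannot meet 5% at n = 2,000 by any estimator of
  this class — a 5% relative error in the upper limit is about one
  standard error there; it needs n ≳ 8,000. Limit errors scale roughly
  with σ·z/√n times the transform's tail derivative, so wide-spread
  analytes simply need more data.
* **Contamination robustness.** Across 20 scenarios (5–20% pathological
  fraction, +2.5 to +4 SD shift, 1.5× width) at n = 2,000, the indirect
  upper limit's mean absolute error is 8.5 units against 20.8 for the
  naive empirical 97.5th percentile, winning all 20 scenarios. Bias grows
  with the contaminated fraction; at ~19% contamination the upper limit
  still overshoots by ~25% (the window's top quantiles begin to absorb
  pathological mass) while the naive percentile overshoots by ~40%.
* **Bootstrap CI coverage.** The upper limit's 95% percentile-bootstrap CI
  covers the generating 97.5th percentile in 38/40 Monte-Carlo
  repetitions (n = 2,000, B = 200).

An early design scored each power by a chi-square histogram statistic over
the model's central region with μ = median and σ = IQR/1.349. It was
abandoned after simulation showed the central histogram identifies λ poorly
(sd ≈ 0.3) and — worse — strongly negative powers can "squash" a
contaminated upper flank into apparent symmetry and win the search,
occasionally selecting models whose 95% interval does not even lie in the
transform's range. The quantile–quantile cost with the domain guard removes
that failure mode.

## Synthetic cohorts

The generator emulates a pediatric outpatient cohort: per analyte and sex,
a healthy component that is Normal(μ(age), σ) on a Box-Cox(λ) scale with a
piecewise-linear age trend in μ only (constant σ — the simplest family in
the estimator's model class, keeping every recovery test exact against
closed forms), plus, with probability 19.2% by default (the typical
excluded-abnormal share of a screening intake, ~935/4,868), a pathological
component shifted +3σ and widened 1.5× on the same transformed scale —
one-sided elevation, the common deficiency/excess screening scenario,
chosen to stress the upper limit.

Default calibration: whole-cohort medians at the cohort's median age
(48 months) equal the reported panel medians (Cu 19.74 µmol/L, Zn 74.80,
Ca 1.60 mmol/L, Mg 1.52, Fe 7.84, Pb 126.09 — units stored as opaque
labels); age-trend directions are Cu and Ca falling through childhood, Zn
and Fe rising, Mg flat, Pb falling with a late-adolescent rise; transformed
scale σ set so the healthy spread roughly reproduces the reported cohort
IQRs; powers λ = 0.5 (Cu, Zn), 1 (Ca, Mg, Fe), 0 (Pb). The age-frequency
profile peaks at 1–<2 years (17.7%) and is sparse above 14 years; the
printed bin percentages sum to 100.01% from rounding, so weights are
renormalised at construction. Sex ratio 56.32% male; female levels are
offset by −0.10 to +0.05 healthy SD depending on analyte. Ages are integer
months, bins half-open: "1 to <2 years" is [12, 24).

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: analytical imprecision and batch/center
effects, age-varying spread or skewness within a stratum, bilateral or
age-dependent contamination, within-subject correlation across analytes
beyond shared demographics, and seasonal or secular drift. Tests against
this generator validate the statistical machinery, not any particular
laboratory's biology.

Draws whose back-transformed value would be non-positive (outside the
Box-Cox domain) are resampled with a logged count; generation is
bit-reproducible given (config, seed).

## Pipeline and reporting

`run_pipeline` applies, per analyte × sex: clean → tree proposal → validated
refinement → per-bin fit with bootstrap CIs, emitting one report row per
final bin (age labels in the conventional months/years style, e.g.
"3 mths–11 mths", round-tripping exactly to the month interval) plus the
full decision audit. Strata with fewer than 2·min_leaf records fall back to
a single flagged bin. Per-bin bootstrap seeds are derived from the pipeline
seed via numpy's SeedSequence, so reports are byte-reproducible. Simulation
sizes used in the test suite (cohorts of 800–4,000, 40–50 seed replicates,
B = 100–200) keep the whole suite near 20 seconds while leaving the
statistical assertions comfortably powered.
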