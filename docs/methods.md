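# Methods

## Zeitgeber time

Expression snapshots from postmortem donors are aligned on a biological
clock by expressing each death time relative to sunrise at the death place.
Local clock time is converted to UTC as `UTC = local − tz_offset − 1 h·dst`;
the timezone offset and daylight-saving flag are caller-supplied (no
historical timezone database is consulted). Sunrise is computed with the
NOAA sunrise-calculator ephemeris (Julian-century polynomials for the
geometric mean longitude and anomaly, equation of center, apparent
longitude, and nutation-corrected obliquity), accurate to a few thousandths
of a degree; the closed-form hour-angle inversion is refined over three
iterations and agrees with an independent minute-scanning root finder to a
few seconds at mid-latitudes. The sunrise threshold is an apparent solar
elevation of −0.833° (refraction + solar radius), further depressed by the
horizon dip `1.76°·√(elevation_m)/60` for elevated sites. This is the
package's own convention — official-sunrise vs. civil-twilight anchoring is
a genuine free choice for this analysis and is documented rather than
inferred.

ZT is the signed hour distance from sunrise on [−6, 18): *t* hours after
the previous sunrise when `0 ≤ t < 18`, else the negative count-down to the
next sunrise. Because consecutive sunrises are not exactly 24 h apart, the
second branch can drift slightly past −6; values are wrapped back into
[−6, 18) and a warning is logged when the adjustment exceeds 0.25 h.
ZT 0 (death exactly at sunrise) is assigned to the day side. Day is
ZT ∈ [0, 12), night is the rest of the scale (ZT 12–24 in the 0–24
parameterisation); both windows are half-open. Subjects with a precomputed
ZT bypass the solar computation. Polar regimes (no sunrise within ±48 h)
raise an error rather than guessing.

## Preprocessing

Counts are filtered to genes with CPM strictly greater than 1 (configurable)
in at least 50% of subjects, excluding Y-chromosome genes and genes without
identifiers, then transformed to `log2(CPM + 0.5)`; the pseudocount is the
package's choice and is configurable. Site (brain-bank) batch effects are
removed with a parametric empirical-Bayes location-scale adjustment:
per-gene data are standardised by the design-weighted grand mean and the
pooled residual variance after site means; per-site per-gene mean and
variance effects are shrunk toward across-gene normal / inverse-gamma
priors (method-of-moments hyperparameters, iterated to convergence) and
removed. Per-gene grand means are restored exactly after adjustment. Genes
with no within-site variance receive a location-only adjustment. A
`center` method (per-site mean-centering) and `none` are available as
fallbacks. Matched case/control cohorts are built by minimum-cost
assignment (Hungarian algorithm) within exact-match strata on sex and site,
with squared standardised distances on age, PMI, pH and circular ZT plus a
0/1 race penalty; shortage of controls in any stratum is an error naming
the stratum.

## Rhythmicity

The diurnal model is `y = A sin(ft + p) + b` with fixed `f = π/12` rad/h.
With fixed frequency the model is linear in `(c₁, c₂, b) = (A cos p,
A sin p, b)`, so the default engine solves the sin/cos ordinary least
squares exactly and converts back (`A = √(c₁²+c₂²)`, `p = atan2(c₂, c₁)`,
canonicalised to `A ≥ 0`, `p ∈ [0, 2π)`); a Levenberg–Marquardt engine
with eight phase starts is provided for cross-checking and must agree to
1e-6 in RSS. `R² = 1 − RSS_m/RSS_0` is clipped to [0, 1]; the peak hour is
`((π/2 − p)/f) mod 24`. Fits require at least 6 subjects, and a warning is
issued when the ZT span is under 4 h (the design barely constrains phase).

The null distribution pools R² over all genes and shuffles: each shuffle
draws one ZT permutation applied to every gene, preserving gene–gene
correlation under the null. The empirical p uses the add-one correction
`(1 + #{null ≥ obs}) / (1 + |null|)` so p is never zero; BH FDR is applied
across genes. The default is 1000 shuffles; the test suite and acceptance
script use 200, which changes p-value resolution but not calibration (the
pure-noise false-positive fraction at p < 0.05 stays within [0.035, 0.065]
at 2000 genes).

ΔR² = R²_case − R²_ctrl is tested against a paired null: shuffle *k* of the
case cohort minus shuffle *k* of the control cohort, per gene, pooled over
genes and shuffles; p is two-sided by add-one counting of |null| ≥ |obs|.
Loss requires control-rhythmicity (empirical p < α) with significant
negative ΔR²; gain the converse. The pairing scheme and two-sided tail are
the package's decisions and are recorded in output headers. Phase,
amplitude and base differences are compared only for genes rhythmic in both
cohorts, with phase differences taken circularly in (−12, 12] and p-values
from diagnosis-label permutations with per-group refitting.

## RRHO

Both gene lists are ranked by descending −log10(p) with lexicographic
tie-breaks. For every rank-threshold pair (multiples of a step size
defaulting to ⌊N/100⌋) the overlap of the two top lists is scored with the
exact upper-tail hypergeometric probability; the map holds −log10(p) with
the origin at the most-significant corner. Overlap counts come from a 2-D
cumulative histogram of joint rank positions, so the map costs
O(N²/step² + N). Only over-enrichment is scored, and no multiplicity
correction is applied across the map — it is a display statistic, noted in
the output header.

## Stratified differential expression

Within a death-time stratum each gene receives its own linear model:
diagnosis always included, plus an exhaustively selected subset of at most
two covariates from {PMI, RIN, sex, medication, age, pH} minimising
`BIC = n·ln(RSS/n) + k·ln(n)` (k counts intercept, diagnosis and
covariates; ties favour fewer covariates, then lexicographic order).
Race and site are excluded by default because cohorts are matched on them.
Covariates with missing values, constant columns, and rank-deficient
designs are dropped with warnings. A covariate with no variation inside
one diagnosis group (e.g. a medication flag that is identically false in
controls) is also dropped: such a column is a relabelled subset indicator
of the other group, its coefficient competes directly with the diagnosis
effect, and — because label permutations break the covariate–diagnosis
link — the permutation null is no longer exchangeable with the observed
statistic, which we found inflates corrected p-values in calibration
simulations.

The parametric diagnosis p from a selected model is biased by the
selection, so the reported p is a label-permutation corrected p: diagnosis
labels are permuted, the full procedure (selection + fit, by default;
`reselect=False` reuses the observed selection) is re-run, and the add-one
fraction of permuted p ≤ observed p is reported. Storey q-values are
computed over the corrected p's with π̂0 from a cubic smoother of π̂0(λ)
over λ ∈ {0.05, …, 0.95} evaluated at λ = 0.95, a bootstrap λ choice below
50 p-values, and clamping into (0, 1]. Per-term variance fractions are
sequential (type-I) sums of squares with diagnosis entered last, divided by
the total sum of squares. Day/night overlap of DE gene lists is tested with
the two-sided Fisher exact test on the 2×2 membership table.

## Summaries

The gene-set Z-score profile Z-scores each set gene across subjects
(population sd, ddof 0, configurable) and averages over set genes per
subject; a sinusoid fitted to the profile summarises set-level rhythm. Set
members resolve by gene ID first, then symbol. Phase concordance between
two peak-hour lists counts raw differences ≤ 5 h or ≥ 20 h as concordant —
deliberately the literal asymmetric window, kept as the field's convention.
Rhythmic-gene heatmaps order genes by peak hour and subjects by ZT with
per-gene Z-scored entries, and support plotting one cohort's gene list
against the other cohort's subjects. k-means clustering of Z-scored
rhythmic genes uses k-means++ with 20 restarts and a fixed seed; k defaults
to 2.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: log2-CPM-like
values for 10³–10⁴ genes over ~10² subjects, each sampled once at death.
Gene classes are assigned in blocks so truth counts are exact: shared
rhythmic, gain (case-only), loss (control-only), night-only DE,
day-and-night DE, an optional coherent gene set (case-only rhythm with a
common peak), and null. Expression is
`b_g + batch_g(site) + A_g(group)·sin(f·zt + p_g(group)) + δ_g·1[case ∧
window] + noise`, with offsets uniform on 2–10 log2 units, per-gene-site
batch shifts Normal(0, 0.3), Gaussian noise on the log2 scale (sd 1.0 by
default; a Student-t option stresses the permutation machinery), rhythm
amplitude 1.5 and DE effect 1.0 log2 units by default. Death times follow
a wrapped-normal mixture (60% morning, ZT 2 ± 2.5 h; 40% late evening,
ZT 15 ± 2.5 h) to mimic real death-time clustering; uniform sampling is
used for calibration, and exact per-group night-death counts can be
requested for stratified designs. Sites alternate in equal proportions
within each group, matching the matched-cohort design. Death-place records
target a uniform ZT and construct the local death time from the actual
sunrise at a sampled mid-latitude site, so rederiving ZT through the solar
module recovers the target.

What the generator does not emulate: library-size and compositional
artifacts, count discreteness and mean-variance coupling, cell-type
heterogeneity, correlated gene modules beyond the shared-phase set, and
realistic covariate–expression dependence (covariates are drawn
independently of expression unless a confounder is injected). Passing
tests therefore demonstrate correctness and calibration of the machinery
under the stated generative model, not performance on real tissue.

## Problem sizes and numerical choices

The test suite and acceptance script run scaled-down designs chosen as
representative: 200 ZT shuffles (vs. the 1000-shuffle default), 2000-gene
cohorts for calibration and gain/loss recovery, 200-gene × 500-permutation
stratified DE with 16 + 16 night-death subjects, and a 1000-gene demo
pipeline for bit-level determinism. All randomness flows from one master
seed through per-stage SHA-256-derived child seeds, so every stage is
independently rerunnable and the full pipeline is bit-identical under a
fixed seed. Degenerate inputs are handled explicitly: constant expression
fits flat with R² = 0, zero-variance genes get zero variance fractions,
empty rhythmic sets give empty heatmaps with warnings, and infeasible
matching or polar-death geometries raise errors rather than guessing.

## Known limitations

ZT anchoring ignores the donors' actual light exposure and assumes
entrainment to local sunrise. Label permutation in the stratified DE is
exact only under exchangeability; strong covariate–diagnosis dependence is
guarded against (see above) but moderate dependence can still distort
corrected p's. The ΔR² null pairing assumes the two cohorts' shuffle
streams are comparable shuffle-by-shuffle; any pairing of independent
streams is valid, but alternatives (e.g. all-pairs pooling) would give
slightly different tail resolution. Periods other than 24 h are out of
scope, as are nonparametric rhythm tests.
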