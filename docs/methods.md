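# Methods

This note documents the models, numerical choices and limitations of the
`vhi` package in the package's own terms.

## Components and curve fits

**Dilator capacity.** Acetylcholine concentration–response data (seven
half-log doses, 10⁻⁹–10⁻⁶ M) are fit with the three-parameter base-10
logistic `y = min + (max − min)/(1 + 10^(logEC50 − x))`. The slope is fixed
at one: the tabulated component values are consistent with this form and a
Hill-coefficient extension would change the meaning of `logEC50`. The fit
minimizes the sum of squared residuals with a trust-region least-squares
solver; initial values are `min(y)`, `max(y)` and `median(x)`, the upper
bound is constrained to lie at or above the lower bound
(parameterized as `min + delta`, `delta ≥ 0`), and `logEC50` is boxed to
`[min(x) − 2, max(x) + 2]` so an essentially flat series cannot push the
midpoint to infinity. The default SSE tolerance is 1e-8. Optimizer failure
is reported as `converged = False` in the fit object rather than raised,
because a failed animal should drop out of a cohort, not abort it. The
fitted **upper bound** (μm) is the component carried downstream. The fit
operates on whatever response column is supplied — absolute diameter or
diameter change — and does not reinterpret units.

**Wall stiffness.** Passive pressure–diameter series use 5 mmHg as the
"0 mmHg" reference point followed by 20-mmHg steps to 160 mmHg.
Stress and strain use the standard thin-wall definitions for this
preparation: `σ = P·ID/(2·WT)` with `WT = (OD − ID)/2`, and
`ε = (ID − ID₀)/ID₀` with `ID₀` the inner diameter at the 5 mmHg reference,
so the first strain is exactly zero. Pressure converts at
1 mmHg = 1333.22 dyn/cm², exposed as a parameter. The exponential growth
relation `σ = σ₀·e^(βε)` is fit as ordinary least squares of `ln σ` on `ε`
(log-linear OLS, matching how such fits are quality-gated by r²) rather
than nonlinear least squares on the raw scale; `β` is scale-free under this
choice, `ln σ₀` is not. Fits with `r² ≤ 0.85` are flagged `acceptable =
False`. The choice of stress unit therefore affects only the intercept.

## Index construction

Component scores are percent-of-ideal against the arithmetic mean of
untreated LZR animals in the same (age, bed) stratum: `100·m/s` for
components that decrease with disease (dilation, MVD) and
`100 + (100 − 100·m/s)` for stiffness, treating an excess above the
standard as an equal deficit. Scores are **not clamped**: a stiffness score
below zero (β more than twice the standard) is meaningful signal. An
opt-in `clamp_zero` floor exists for users who want bounded scores.
Animals missing any component are excluded with a warning; no imputation.

**Percentage mode** (default) averages the three scores per animal; it is
exactly reproducible from published group means, which is why the worked
examples and the deterministic treatment-effect computation use it.

**Percentile mode** converts each component's percentage scores to Hazen
percentile ranks, `100·(i − 0.5)/n`, with ties sharing their mean rank
(so a complete tie maps to 50 and the rank mean is always exactly 50),
within the pooled population of **all animals of one (age, bed) stratum in
the scoring run**. The pooling population had to be decided here: ranking
within a single experimental run's age-matched pool is what makes an
animal's score "relative to the specific control values from the original
experiment," and it makes the mode self-contained. The mean of the three
ranks is rescaled by the pooled LZR mean so the LZR cohort is exactly 100
by definition. Rank normalization exists because β routinely reaches
multiples of the healthy value while dilation and MVD shift by tens of
percent; ranking prevents wall mechanics from dominating the composite.
Any order-preserving rescaling of a component leaves every rank — and hence
the index — unchanged.

Cohort summaries report mean ± SE (sample SD/√n). The all-ages
("time-averaged") value per group is the unweighted mean of its per-age
cohort means, with SE propagated as `√(Σ seᵢ²)/k` since ages are disjoint
animal sets. Treatment effects are `100·(treated − untreated)/untreated`
on matched strata.

## Validity statistics

* **Criterion validity:** Pearson correlation of the index with plasma
  insulin or TNF-α, p from the t transform with n − 2 df; a verdict passes
  when `r ≤ threshold` for a user-chosen negative threshold (no published
  numeric r exists to fix it, so it is a parameter, default −0.4 in the
  pipeline).
* **Group differences:** one-way ANOVA (hand sums of squares so the
  all-identical degenerate case returns F = 0, p = 1) followed by
  **Newman–Keuls**: means ordered, stepwise studentized-range tests with
  span-dependent critical values `q(α, span, df_within)` computed
  numerically from `scipy.stats.studentized_range` (printed q-tables are
  used only as independent test oracles); the standard error uses MS_within
  and, for unequal n, the harmonic mean of the pair's sizes — Newman–Keuls
  has no canonical unbalanced form and this is the common convention. The
  containment rule is enforced: pairs inside a non-rejected span are marked
  non-significant without testing. α is fixed at 0.05 throughout the
  pipeline, matching the convention of the cohort tables. Null simulations
  put the familywise error at ≈0.05 for three groups.
* **Discriminant validity:** the ordering LZR > OZR > OZR+L-NAME of cohort
  means in one stratum; L-NAME removes nitric-oxide bioavailability and
  accelerates vasculopathy, so an index that cannot rank it below untreated
  OZR is not measuring health.

Repeated-measures ANOVA is out of scope: no within-animal repeated data
survives into this data model.

## Synthetic cohorts

The generator emulates the study's cohorts from a packaged fixture
(`vhi/data/cohort_tables.csv`) holding each printed (group, age, bed) cell:
component means ± SE, biomarker means ± SE and the published sample size
`n`, used to reconstruct SDs as `SE·√n`. Cells the source tables leave
blank are absent. Two kinds of cells are themselves synthetic and flagged
in the fixture's `synthetic_fields` column: TNF-α levels (no summaries are
published; placeholders in arbitrary units rise from 100 ± 5 in LZR to 2×
in late OZR — only their *coupling* matters downstream) and the
pentoxifylline component cells (no component summaries are published;
copied from the TEMPOL cohort, the other agent of the same
antioxidant/anti-inflammatory class reported as comparably effective).
Where a treated group lacks published biomarkers, the untreated OZR values
are reused and flagged.

Per animal, a single latent health factor `z ~ N(0,1)` drives all coupled
quantities: `value = mean + SD·(s·ρ·z + √(1−ρ²)·ε)` with the sign `s`
chosen so larger `z` is healthier (raises dilation and MVD, lowers β,
insulin, glucose and TNF-α; body mass is uncoupled). The default coupling
ρ = 0.7 reproduces index-vs-insulin correlations near −0.55 in a single
OZR stratum, the qualitative structure of the criterion-validity scatter;
ρ = 0 gives |r| consistent with independence. Coupling is assessed within
one (age, bed) stratum: pooling ages would manufacture a negative
correlation from the age trends alone, even at ρ = 0, and would not test
the mechanism. Non-positive draws are rejected and redrawn (rare at
table-calibrated parameters).

Raw series are generated by forward models so the fitting stages close the
loop: dose-response series from the logistic with the animal's dilation
bound as `max` (baseline diameter 60% of the cohort mean bound, logEC50 ~
N(−7.5, 0.15), 1 μm observation noise); mechanics series by solving the
stress balance `P·ID/(2·WT) = σ₀·e^(βε)` for ID at each grid pressure with
wall cross-sectional area conserved (bisection/Brent to near machine
precision), geometry 90/12 μm (ID₀/WT₀, skeletal) or 120/15 μm (cerebral),
σ₀ derived from the 5 mmHg reference so the reference strain is exactly
zero, 0.5 μm diameter noise. Noise-free, the round trip recovers β to
~1e-13 relative error. The 80%-of-MAP equilibration step of the wet
protocol is not modelled; series are generated directly on the analysis
grids.

**What passing tests do not show:** the generator draws components from
Gaussian summaries and couples them through one latent factor; real animals
have heavier tails, age-correlated trajectories (here ages are independent
cross-sections, as in the source design), drug pharmacokinetics and
between-laboratory variation, none of which are modelled. Calibration tests
show the pipeline recovers what the generator encodes — not that the
generator is the biology.

Determinism: every cohort derives its RNG from (seed, group, age, bed) via
`numpy` SeedSequence with a CRC-32 stream key, so a study bundle is a pure
function of (specs, seed) and is stable under reordering of the spec list.

## Problem sizes and defaults

Acceptance-style computations use the sizes that make their statistics
meaningful at desk scale: n = 200 for coupling correlations, n = 20/group
for cohort-separation checks, 2,000 replicates for the Newman–Keuls null
calibration, 50 seeds for the percentile-mode anchoring identity, and the
deterministic mean-level computation for time-averaged treatment ordering.
CSV output carries 6 significant digits, below every tolerance used in
tests.

## Known limitations

* The percentile-mode reference population is a design choice (pooled
  stratum within one run); scores are comparable across runs only in
  percentage mode.
* Newman–Keuls does not control the familywise error strictly for some
  configurations with ≥ 4 groups and partial nulls; it is provided because
  it is the procedure the cohort tables' significance markers use, not as a
  recommendation over Tukey HSD.
* The β fit assumes positive stresses and at least three pressure steps;
  vessels with non-physical wall geometry (OD ≤ ID) are rejected at the
  data layer with the offending line.
* Active (myogenic, constrictor) responses and shear-dependent dilation are
  outside the data model; only the passive mechanics and the acetylcholine
  dilator curve are represented.
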