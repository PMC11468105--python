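# Methods

## The longevity measure

The realized probability of dying (RPD) compares one person's observed
survival with that of their age- and sex-matched peers in a reference
population.  Given a period life table of annual death probabilities
q(sex, age, calendar year), a subject of sex s aged a at baseline who is
followed for n calendar years has

    RPD = (1 − d₁) · (1 − d₂) · ⋯ · (1 − dₙ),

where dᵢ = q(s, a + i − 1, baseline_year + i − 1) — attained age advances
exactly one year per calendar year, and the baseline year counts as
follow-up year i = 1.  RPD is the fraction of the matched life-table
cohort still alive at the subject's death: values near 1 mean dying
before almost all peers, values near 0 mean outliving almost all of them.
The regression analysis uses the logit, LRPD = ln(RPD/(1 − RPD)), with
the natural logarithm (the standard logit convention).

Three conventions the annual formula leaves open are fixed as follows and
are deliberate package choices:

* **The death year contributes a full factor** (n = death_year −
  baseline_year + 1), so RPD is the cohort fraction alive at the *end* of
  the death year.  Day-level dates are not modelled; with annual
  probabilities this is the only convention under which RPD is itself a
  product of whole-year survival terms.  A death in the baseline calendar
  year yields n = 1.
* **Censored subjects** (alive at the study's end) receive an imputed
  RPD: the *cumulative* life-table survival from baseline through the
  final follow-up year multiplied by 0.50 — half of the still-alive
  cohort fraction, i.e. the expectation if the subject's eventual death
  rank is uniform among the survivors.  An alternative reading (single
  final-year survival × 0.50) is available as
  `impute_rpd_censored(..., variant="final_year")`; it is not the default
  because it is not commensurate with the observed-death RPDs, which are
  cumulative cohort fractions.
* **No extrapolation**: any query outside the life table's declared age
  or year range is a hard error.  Silent extrapolation would corrupt RPD
  values without any visible symptom.

Under the null — death years drawn from the same table used for scoring,
no censoring — RPD is uniform on (0, 1) up to annual discretization.
Exactly, E[RPD] = (1 − Σᵢ ΔSᵢ²)/2 where ΔSᵢ is the probability of dying
in follow-up year i; the deficit from 0.50 is about q/4 for the typical
annual death probability q near the modal death ages.  The package's
fine-grained null table (Gompertz hazard capped at q = 0.02) therefore
has an exact null mean of 0.495 at every baseline age 60–89 and both
sexes; a cap as high as 0.15 would push the exact mean down to ≈0.46 for
the oldest baseline ages.  This is why `null_study_cohort` uses the 0.02
cap: the choice follows from the closed form, not from simulation.

## The regression tree

The outcome LRPD is modelled by binary recursive partitioning with the
variance-reduction criterion: at each node, over all predictors and all
candidate binary rules, choose the rule maximizing

    ΔSSE = SSE(parent) − SSE(left) − SSE(right),

evaluated on the node's subjects with that predictor observed (missing
values never participate in split selection).  Ordered predictors
(continuous and ordinal, including the three-level change codes) use
threshold rules `x < c` with c at midpoints between consecutive distinct
observed values.  Nominal predictors use category-subset rules; for up
to 10 observed categories every binary partition is scored exhaustively,
because the textbook mean-ordering reduction is provably optimal only
without a minimum-leaf-size constraint — under `minleafsize > 1` the
constrained optimum can be non-contiguous in the category-mean ordering
(our exhaustive oracle test exposed exactly this).  Wider nominals fall
back to the mean-ordering scan.

Stopping follows three rules, with presets mirroring the defaults and
the sensitivity setting of the HPSPLIT-style procedure this emulates:

| parameter     | default | sensitivity | meaning                                   |
|---------------|---------|-------------|-------------------------------------------|
| `maxdepth`    | 5       | 10          | maximum number of split levels below root |
| `minleafsize` | 1       | 10          | minimum observed subjects per child       |
| `minvariance` | 1e-8    | 0.01        | minimum node outcome variance (SSE/n) to split |

There is no cost-complexity pruning: trees are grown to the stopping
criterion, and cross-validation is used to assess (not tune) the model.

**Determinism.** Ties between candidate splits go to the earlier
predictor column, then the smaller threshold (the subset enumeration
order fixes nominal ties).  Identical inputs and hyperparameters give a
byte-identical serialized tree.

**Missing-value routing.** A subject whose primary split variable is
missing is routed by *surrogate* rules: splits on other variables ranked
by their agreement with the primary split among subjects where both are
observed (both orientations are tried for numeric surrogates; only
surrogates strictly beating the go-with-the-majority baseline are kept,
at most five per node).  The final fallback is the branch that received
the majority of the node.  Surrogates are computed only at nodes that
actually contain missing primary values; at other nodes a future missing
value falls directly to the majority branch — computing surrogates
everywhere would roughly double the fit cost for a path that training
data at that node never exercises.  The vendor procedure's exact
assignment algorithm is not documented; surrogate-with-majority-fallback
is one concrete reading of routing "based on observed predictor
similarities".  Surrogate use does not contribute to importance.

**Importance** of a variable is the sum of ΔSSE over its primary splits,
normalized so shares sum to 100, reported with the count of primary
splits on that variable.  Variables never split on are omitted.

**Cross-validation.** 10-fold, simple random folds (sizes differing by
at most one) fixed by a logged seed; the tree is regrown on each
complement and held-out squared errors are pooled over subjects,
ASE = (1/n) Σ (yᵢ − ŷ₋fold(i))².  A per-fold mean is also reported since
published ASE figures are ambiguous between the two.

## Change variables

For predictors measured at both waves (baseline and ten years later),
the change is coded either as a three-level ordered variable —
worsened (−1) < unchanged (0) < improved (+1), the sign of
(wave2 − wave1) mapped through the variable's direction — or as the raw
difference wave2 − wave1.  The default ("auto") uses three levels for
short ordinal scales (≤ 5 levels) and the raw difference for wide score
scales, where a tree can meaningfully cut inside the score range; both
representations can be forced.  Nominal variables are never change-coded.
A change value is missing whenever either wave is missing — in
particular for every subject dead before the second wave; those subjects
are *retained* in the changes analysis and routed by the missing policy,
so the tree can fall back on baseline structure.

## The synthetic cohort generator

Because the original cohort is available only on request, all end-to-end
runs use simulated data shaped to the study frame: n = 1056 subjects
aged 60–89 (uniform) at baseline 1979, 49.8% male, vital status through
2014, a second survey in 1989 among survivors.  Mortality follows a
year-invariant Gompertz period table q(a) = min(cap, α_sex·e^{βa}) with
α_f = 2·10⁻⁵, α_m = 3.5·10⁻⁵, β = 0.095, cap 0.7 — plumbing values at
which the cohort is nearly extinct after 35 years (≈2% alive, matching
the study's ≈1% order of magnitude), not calibrated national rates.
Predictor effects act on the annual death probability through the
complement power q_i = 1 − (1 − q)^{HR}, which keeps q_i a valid
probability for any hazard ratio HR > 0.

Per subject, log HR = 0.25·z + 0.008·smoking_years −
0.04·demanding_functioning + 0.05·medications (linear terms centered)
+ 0.45·1[srh < 2], where z ~ N(0,1) is a single shared latent frailty
factor that also loads on the survey variables (worse self-rated health,
mobility, functioning and ADL; more medications and musculoskeletal
disease at higher z), making predictors mutually correlated.  Effect
sizes are modest-to-strong values typical of gerontological cohorts
(poor self-rated health HR ≈ 1.6); they are configuration, not claims.
Wave-2 values move by worsening-biased transitions (worsen/stay/improve
= 0.35/0.50/0.15) clipped to each scale; 2% of wave-1 and 3% of wave-2
survivor values are missing at random.

The planted scenarios switch all incidental effects off: `root_only`
keeps only srh < 2 → HR 2.5; `two_level` adds, among good-SRH subjects,
education ≥ 9 years → HR 1/2.2.  Ground truth is returned so recovery
studies can assert the fitted structure.

What the generator does *not* emulate: day-level death dates, calendar
trends in mortality, informative (non-death) dropout, item-level
missingness mechanisms that depend on health, measurement error in the
life table, and the full 49-variable survey battery (a 10-variable
typed subset stands in).  Passing tests therefore demonstrate the
pipeline's correctness and statistical behaviour under these idealized
conditions, not agreement with the restricted cohort's published
figures, which are out of scope.

## Problem sizes used in the shipped analyses

The numbered drivers under `analysis/` run the full n = 1056 frame.
The null study uses 100,000 subjects (the mean's Monte-Carlo SE is
≈0.0009, an order below the 0.01 acceptance band).  Split-recovery uses
200 replicates of n = 1000 for the root scenario and 100 for the
two-level scenario; the exhaustive split-oracle comparison uses 100
random datasets of n ≤ 50 with four mixed-type predictors, sizes at
which the brute-force enumeration is itself trustworthy.

## Known limitations

* Annual granularity: RPD cannot distinguish deaths within the same
  calendar year; the full-factor convention shifts all RPDs slightly
  downward relative to an exact-date definition.
* The surrogate policy is one plausible reading of the vendor's
  undocumented missing-value assignment; trees fitted to data with heavy
  missingness may route differently than the original procedure.
* Degenerate RPD = 1 (possible only on zero-hazard toy tables) has no
  finite logit; such subjects are excluded from tree fitting with a
  logged warning rather than clamped.
* No pruning, classification targets, multiway splits or ensembles; a
  pruning hook is the natural next extension.
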