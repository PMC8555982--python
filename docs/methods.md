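# Methods

## Behavioral model

Choices are modeled per session as a logistic regression on juice
quantities and four indicator contrasts. With qA, qB the offered
quantities, and δ-indicators for low cost, previous-trial juice,
previous-trial cost level, and left-side placement of each juice's offer
and target:

    P(choice B) = 1 / (1 + exp(−X))
    X = a0·qB − a1·qA + a2(δB,+ − δA,+) + a3(δn−1,B − δn−1,A)
        + a4(δcostB=prev − δcostA=prev) + a5(δofferB,L − δofferA,L)
        + a6(δtargetB,L − δtargetA,L)

Every normalized coefficient is a value in units of juice B: ρ = a1/a0
(relative value of A), ξ = a2/a0 (action cost; the value equivalent of
avoiding the long saccade), η = a3/a0 and φ = a4/a0 (juice and cost
hysteresis), δ = a5/a0 and ε = a6/a0 (offer- and target-side biases). The
hysteresis contrasts are zero on the first trial of a session. ρ is the
qB:qA ratio at indifference; a0 acts as an inverse temperature.

**Estimation.** Unpenalized maximum likelihood. The log-likelihood of a
logistic model is concave, but near-deterministic sessions push
coefficients to infinity (complete separation), so the optimizer is
L-BFGS-B with box bounds ±50 (a0 ∈ (0, 50], keeping the normalized
parameters defined), started from three fixed initializations; a fit that
lands on a bound is flagged `converged=False` with a warning. The fit is
cross-checked against an unbounded logistic regression from statsmodels in
the tests. Preconditions: at least two distinct offer types and at least
one choice of each juice, otherwise ρ is unidentified and the fit is
refused. Juice B is by convention the lower-valued juice (ρ ≥ 1 in typical
sessions); this is a labeling convention of the input data, not inferred.

**Per-condition choice patterns.** For display and indifference points the
model is refitted with the hysteresis and spatial terms removed (quantity
and cost terms only), and trials are split by the cost level of juice A.
The indifference point per condition solves X = 0 at qA = 1:
ratio = ρₛ ∓ ξₛ for A at high/low cost.

## Decision variables

Twenty-one candidate variables are computed once per trial from the offers,
the choice, the spatial configuration, and the session's fitted (ρ, ξ).
Offer values are cost-discounted: offer value A = ρ·qA + ξ·[A low cost],
offer value B = qB + ξ·[B low cost]; the low-cost offer earns the bonus ξ.
The variables span juice-based (offer value A/B, chosen juice), cost-based
(offer value −/+, chosen cost), visuospatial (offer value L/R, offer
locations) and action-based (target-value, target-location) reference
frames, plus chosen value, value ratio (other/chosen; undefined when the
chosen value is 0, in which case the trial is excluded pairwise for that
variable only), spatial congruence, and a cost/benefit-conflict flag set
to 1 exactly when the high-cost offer carries the higher offer value. Two
binary covariates code whether the chosen offer and the chosen target lie
in the hemifield contralateral to the recorded hemisphere (supplied per
session in the configuration; both hemispheres may appear in one dataset).
Target angles are reduced to a binary hemifield at ingestion; the raw angle
is retained but unused.

## Time windows and task-relatedness

Nine 0.5 s windows are aligned to behavioral events: pre-offer, post-offer,
late-delay (0.5–1.0 s after offer onset), mem-delay (after offer offset),
pre-target, post-target, pre-go, pre-juice, post-juice. Windows are
half-open [start, start+0.5) so boundary spikes are counted once. A
*response* is one neuron's rate in one window as a function of the trial.

Each response enters two 3-way ANOVAs — (trial type × offer A location ×
target A location) and (trial type × chosen offer location × chosen target
location) — main effects only, type II sums of squares; a response is task
related if any factor reaches p < 0.001 in either ANOVA (the trial-type
factor appears in both; its smaller p is kept). Main-effects-only type II
was chosen because the factor lists carry no interactions and the
pseudo-random counterbalancing leaves mild imbalance; with no interaction
terms, type II equals drop-one partial sums of squares, which is how it is
computed (projection onto precomputed orthonormal design bases, reused
across all neurons of a session — verified against `anova_lm(typ=2)`).
Trial types with fewer than 2 trials are dropped; a factor constant over
the retained trials gets p = 1 with a warning.

## Tuning classification (ANCOVA)

Data points are per-(trial type × covariate level) mean rates, cells with
at least 2 trials; this matches the granularity at which such tuning is
plotted and summarized. Trial-level fitting is available
(`level="trials"`); it changes p-values, not the R² ordering. The covariate
is the chosen offer location for windows before target onset (the pre-offer
window follows this early convention) and the chosen target location from
target onset on.

* **Parallel-lines model** (variables 1–19): rate ~ variable + group, no
  interaction. The variable *explains* the response if its slope is
  significant at p < 0.05; the recorded R² is the **total** R² of the
  two-regressor model, and is set to 0 when the variable does not explain
  the response.
* **Horizontal-lines model** (the two location-only variables): rate ~
  group. The location-only variable matching the window's covariate is the
  one assessed there (chosen-offer-location-only before target onset,
  chosen-target-location-only after); the other is recorded as not
  assessable in that window. This keeps the horizontal model nested in
  every parallel model of the same response, so its R² is strictly below
  that of any explaining variable — hence a location-only variable can
  provide the best fit only when it provides the sole explanation.

Best fit = argmax of recorded R² over the explained set, with the
sole-explanation rule for location-only variables; ties break by variable
index (logged). Binary variables enter as numeric 0/1 regressors.

**A structural property worth knowing:** a purely location-driven response
is spuriously "explained" by each of the ~19 parallel variables at the
nominal 5% rate, and any such explainer outranks the location-only
variable. With 19 correlated tests the familywise rate is near 50%, so
roughly half of pure location responses are best-fitted by an incidental
variable. The location variable remains the modal best fit and explains
>90% of such responses; population-level selection is unaffected. This
dilution is a property of the classification rule, not of the
implementation.

## Variable selection

The explanatory power of a variable subset is the number of task-related
responses whose explained set it intersects, pooled across all nine
windows. The stepwise procedure selects at each step the variable with the
highest number of best fits within any single time window (a "sum across
windows" scoring is available), removes the responses it explains, and
repeats on the residual data until the best remaining variable's marginal
power falls below 2% of the task-related responses (the threshold scales
with population size; absolute counts are logged). Stepwise ties break by
higher marginal power, then variable index.

The best-subset procedure enumerates all subsets of a given size
(guaranteed optimal; enumeration is capped at size 8). The decision
variables come in strongly collinear families — chosen value equals offer
value B on every B-choice trial (cell-level r ≈ 0.93), so offer value B's
coverage nearly contains chosen value's and chosen juice's. Two
consequences drove the design here. First, distinct subsets routinely tie
in explanatory power; ties break by the subset's total best-fit count,
then lexicographically, anchoring the choice to the same evidence the
stepwise procedure uses. Second, coverage saturates below the generating
set size, which makes a "<2% marginal gain" size rule stop early at a
coverage-equivalent but scientifically different set; the pipeline
therefore compares the two procedures like for like, running best-subset at
the stepwise-selected size. Standalone `best_subset_select` retains the 2%
rule when no size is given.

## Dimensional integration

Two chosen-value variants: cost-affected (the Table-style chosen value,
with ξ) and cost-independent (ξ forced to 0, i.e. ρ·qA or qB of the chosen
juice); they coincide when ξ = 0. A response qualifies when **both**
variants explain it (p < 0.05) — responses where only one side explains are
counted and excluded, avoiding bias toward either variant — and its
assigned R² is the larger of the two. ΔR² = R²_cost-affected −
R²_cost-independent is aggregated by epoch: early = post-offer…pre-target,
late = post-target…post-juice; the pre-offer window belongs to neither. A
neuron tuned in several windows contributes one ΔR² per qualifying window.
Each epoch's distribution is tested against zero with a two-sided Wilcoxon
signed-rank test (mean and median both reported); epochs are compared with
a rank-sum test.

## Population statistics

Across-session medians of ξ, η, φ, δ, ε are tested against zero with
two-sided Wilcoxon signed-rank tests (exact null distribution up to n = 25,
normal approximation above); ρ is reported without a test. No
multiple-testing correction is applied anywhere — thresholds are the raw
0.001 screen, 0.05 explain, and figure-level tests. Cross-area encoding
comparisons use a Pearson χ² on the 2×2 table (df = 1, no continuity
correction); a Fisher exact p is reported alongside when an expected cell
falls below 1. Counts for the comparison area are user-supplied inputs and
never recomputed.

## Synthetic data generator

The generator emulates the study conditions: sessions of counterbalanced
offer types with choices drawn from the logistic model, and neurons whose
windowed rates are linear in one decision variable plus an additive
ipsi/contra location offset, with Poisson counts on rate × 0.5 s.

* **Session defaults**: 250 trials; eight offer types with qB:qA ratios
  0.5–6 around ρ = 2; normalized parameters at the published
  across-session medians (η = 0.16, φ = −0.008, δ = −0.03, ε = 0.017, and
  ξ = 0.22, midway between the two animals' medians of 0.27 and 0.18). ρ
  and a0 are not published per session; ρ = 2 is a typical relative value
  for dissimilar juices and a0 = 2 gives realistic choice stochasticity
  near indifference. The eight cost-by-side configurations (cost
  assignment × offer side × target side) repeat in shuffled blocks of
  eight, so every configuration count is within ±1 of its share; hysteresis
  indicators are computed from the realized choice sequence.
* **Neuron defaults** (five-signal recipe): baseline 6 spikes/s; slope 3
  spikes/s per value unit for chosen-value cells; 8 spikes/s per unit for
  binary-variable cells and for the location offset. These put single-cell
  cell-mean R² in the 0.6–0.9 range of well-tuned cortical examples.
  Location-only cells follow the window's covariate (offer side early,
  target side late), mirroring the reference-frame structure the analysis
  assumes. Mixed tuning is expressible by summing rates of two specs but is
  off by default.

What the generator does **not** emulate: spike-train autocorrelation,
overdispersion (Fano > 1), slow drift, mixed/nonlinear tuning, and
error/aborted trials (inputs are completed trials only; hysteresis terms do
not skip aborted trials because none exist). Passing tests therefore show
that the pipeline recovers what it assumes — linear single-variable tuning
with additive location offsets under Poisson noise — not that real tissue
satisfies those assumptions.

## Numerical choices and problem sizes

Coefficient bounds ±50; ANCOVA cells need ≥2 trials; all regressions are
closed-form least squares with t/F tests (agreement with statsmodels to
1e-10 is asserted in the tests); window boundaries half-open; ties in best
fit and selection break as described above, toward lower variable index
last. Simulation studies in the tests and the acceptance script use
sessions of 250–400 trials, cohorts of 56–141 sessions, and populations of
~70 neurons — sizes matched to the recorded dataset's session and
population scale, at which each study runs in seconds.

## Known limitations

Single-session estimates of the normalized parameters scatter with
standard errors around 0.05–0.1; only across-session medians are expected
to recover generative values. The sole-explanation rule dilutes
response-level location-only best fits (see above). Best-subset enumeration
is exponential in subset size (capped at 8). The ΔR² comparison is defined
for the chosen-value variable only; no other variable gets a variant
analysis. Probit links, hierarchical pooled fits, reaction-time models,
interaction-ANCOVA ("separate lines") models, and information-criterion
selection are out of scope.
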