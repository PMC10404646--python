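# Methods

This note documents the models, conventions, and numerical choices behind
`tripletsl`, in the order the pipeline runs them.

## Task designs

Each statistical-learning (SL) task presents 12 unique stimuli partitioned
at random into 4 ordered triplets. The familiarization stream concatenates
randomized triplet presentations — 24 repetitions per triplet at SOA
1000 ms for the visual tasks (image, letter), 48 repetitions at SOA 480 ms
for the auditory tasks (tone, syllable) — so transitional probability is 1
inside a triplet and much lower at triplet boundaries. Event onsets are
(index − 1) × SOA, in integer-friendly milliseconds; stimulus rendering is
out of scope.

Two points the paradigm leaves open are config-exposed rather than assumed:

* **Triplet adjacency.** By default a triplet may not immediately repeat
  (`allow_immediate_repeat=False`), the common choice in this paradigm; it
  keeps the boundary transitional probability strictly below 1 (each of
  the other triplets is entered with probability ≈ 1/3, so the marginal
  probability of any given triplet following a boundary stays ≈ 1/4).
  Orders are drawn sequentially with probability proportional to remaining
  repetition counts, restarting on dead ends; a single-triplet inventory
  with repeats disallowed is correctly rejected as unsatisfiable.
* **2-AFC presentation order.** Whether the target or the foil plays first
  is balanced 50/50 over the 32 trials and randomized.

**Foils** must preserve each element's within-triplet position while never
occurring in the stream. We recombine by distinct cyclic shifts of a
random relabeling: foil *i* takes its position-*k* element from target
σ_k(*i*), with σ₁, σ₂, σ₃ distinct shifts. Every foil therefore draws its
three elements from three different targets, which maximizes foil–target
separation under the position constraint, guarantees novelty (targets'
elements are disjoint across triplets), and makes all four foils distinct.
Because any aligned 3-window of the stream is a target and any unaligned
window mixes positions (2,3,1) or (3,1,2), foils — which keep positions
(1,2,3) — can never appear as contiguous subsequences; this is also
property-tested.

The detection target is the **third element of one triplet**, drawn
uniformly per task per participant.

## Keypress scoring

Keypresses are accepted from one stimulus before to two after a target
onset: (−SOA, +2·SOA) = −480..+960 ms (auditory) or −1000..+2000 ms
(visual), capturing anticipations and delayed responses. Matching is
one-to-one: it first maximizes the number of matched targets, then
minimizes total |latency|, breaking ties toward the earlier target. For
the shipped designs target spacing (≥ 3 SOA) exactly equals the window
span, so windows are disjoint and each target independently claims its
nearest keypress; when a caller widens the window into overlap, the same
objective is solved exactly via `scipy.optimize.linear_sum_assignment`
(the two paths are property-tested against each other and against
brute-force enumeration). Keypresses matched to no target — including
those inside a target's window that lose the one-to-one competition — are
false alarms, attributed to the stimulus event whose onset interval
contains them.

Sensitivity is Grier's nonparametric A′ (0.5 = chance, 1 = perfect), with
the H < F case mirrored around 0.5. The false-alarm denominator is the
number of non-target stimulus events (the natural count given per-event
false-alarm opportunities); it is exposed in the detection summary.

**Exclusions** (RT analyses only; 2-AFC accuracy is never excluded):
first, fewer than 6 valid keypresses — interpreted as assigned hits, since
only hits carry RT into the slope — removes a participant from that task's
RT analysis; second, among the survivors, A′ strictly below the diagnostic
group's task mean − 3 SD (sample SD). The rules are applied per group ×
task, in that order, and are idempotent. Groups too small for an SD (< 2
unexcluded members) skip the outlier rule with a logged warning. Both
thresholds are configurable.

## Individual learning measures

Hit latencies are z-scored within participant × task (sample SD; zero
variance or < 2 hits is flagged and excluded from slope fitting), and the
**RT slope** is the OLS coefficient of z-RT on target occurrence index
(1..24 visual, 1..48 auditory); negative = acceleration = online learning.
**Offline learning** is the proportion correct over the 32 test trials
(chance 0.5). The **composite SL score** per task averages z(−slope) and
z(accuracy), both z-normed over the whole pooled sample (a config switch
norms within group for sensitivity analyses); **domain composites**
average a participant's four z-normed components (2 reversed slopes, 2
accuracies) per domain. Missing components — skipped tasks, RT-excluded
cells — are handled by available-case averaging, so an RT-excluded child
still contributes accuracy.

## Behavioral simulator

The simulator generates complete cohorts in the exact schemas the scorer
reads, with ground truth recorded for recovery tests.

**RT model.** Latency on target occurrence *t* is baseline + β·*t* +
Normal(0, σ_ms), truncated to the accept window. A subtlety: per-
participant z-norming pins the latency SD at 1, so a stream whose z-scale
slope is *s* over 1..T *necessarily* has z-residual SD √(1 − s²·S̄),
S̄ = T(T+1)/12 — a latent "slope plus independent noise" pair cannot be
reproduced verbatim on the z scale. We therefore *define* the simulator's
`true_rt_slope` as the expected post-z-norm slope and back-compute the
millisecond trend, β = s·σ_ms/√(1 − s²·S̄). Consequences: (i) clean
simulations recover the declared slope without attenuation bias (verified
by Monte-Carlo against the closed-form OLS oracle); (ii) the raw-RT noise
SD influences only millisecond-scale behavior (window truncation), not
z-scale analyses; (iii) |s| is bounded by 1/√S̄ ≈ 0.071 at T = 48 — cohort
draws are clipped at ±0.06. Per-participant slope SE is then
√(1 − s²S̄)/√S_tt ≈ 0.010 (T = 48) or 0.028 (T = 24): visual slopes are
inherently ~3× noisier, which propagates realistically into every
downstream analysis.

Hits occur with probability `hit_prob` (participant-level, default mean
0.85, SD 0.08); anticipations (probability 0.03) are uniform in the
negative window; false alarms fire per non-target event (probability
0.015) uniformly within its SOA — the least-structured null behavior.
False alarms landing inside a target window can displace the true
response; together with anticipations this attenuates recovered slopes by
roughly 20% (auditory) to 30% (visual) relative to ground truth, as real
unfiltered child keypress data would. 2-AFC responses are iid Bernoulli
with the participant's task accuracy.

**Cohorts.** Defaults emulate a two-group school-age web study: 50 TD / 55
ASD; ages Normal(8.63, 1.89) / Normal(8.28, 1.20) clipped to 6–12.6 years;
female proportions 0.56 / 0.18; 12% of children stop after three of the
four tasks (missing completely at random); sentence-recall raw scores
(0–32, Normal(27.26, 4.61) TD / Normal(19.91, 8.18) ASD, with a ceiling
through clipping) present for ~64%; parent-rated language level (ASD only)
below age with probability 0.565. A per-child ability factor carries 35%
of the between-participant variance of true slopes and accuracies (and 30%
of sentence recall), producing the modest cross-task and SL–language
correlations real cohorts show. Group × domain effect means default to a
TD-favoring, linguistic-specific profile (TD linguistic slope −0.020 vs
−0.004 elsewhere except ASD linguistic −0.008; accuracies 0.66/0.66 TD,
0.55/0.63 ASD); between-participant SDs are 0.02 (slope) and 0.12
(accuracy).

What the simulator does **not** emulate: sequential effects beyond the
linear trend (fatigue, attention lapses, post-error slowing), response
device latency, non-Gaussian RT tails, informative missingness, and any
dependence of 2-AFC errors on specific foils. Passing tests therefore
demonstrate the pipeline's correctness and calibration under a plausible
generative model, not distributional claims about real children.

## Group-level inference

Factors are sum-to-zero coded at ±0.5 (TD, linguistic, visual, female
positive), so product terms equal difference-in-differences contrasts and
lower-order terms remain interpretable under interactions; trial order is
centered within task (coefficients keep per-occurrence units; ranges
differ by modality). Numeric coefficients are therefore not expected to
match treatment-coded analyses line for line. Sex is a covariate in every
group-difference model.

* **One-sample learning tests**: slopes vs 0 (one-tailed, less),
  accuracies vs 0.5 (one-tailed, greater); sidedness is recorded in every
  result. Zero-variance input exactly at the null returns t = 0, p = 0.5;
  zero variance elsewhere raises a degenerate-test error.
* **Hit-level RT model**: z-RT ~ group × domain × modality × order (full
  factorial) + sex; random by-participant intercepts plus *uncorrelated*
  domain and modality slopes (variance components). Because z-norming
  removes participant × task means, the true participant-level variances
  are near zero and the REML likelihood is flat at the boundary; the
  uncorrelated parameterization estimates markedly more reliably there
  than a full covariance.
* **Composite model**: composite ~ group × domain × modality + sex, same
  random structure. The random slopes are not decorative: composite
  reliability differs by modality (see RT slope SEs above), and in null
  simulations an intercept-only model under-covers the group × domain
  interaction (~0.087 empirical rejection at α = 0.05 over 150 cohorts)
  while the slope structure restores calibration (0.060 over 300).
* **2-AFC model**: trial-level mixed logistic with random intercepts for
  participants and test items and by-participant domain/modality slopes,
  estimated by variational Bayes (`BinomialBayesMixedGLM`); the table
  reports posterior means/SDs on the log-odds scale with z = mean/SD. A
  constant outcome is flagged as complete separation and not estimated.
* **Development**: score ~ group × domain × standardized age + sex
  (random intercept), then a median split on pooled age (ties → younger,
  deterministic) with per-subgroup group × domain models keeping age as a
  continuous covariate; subgroup sizes and the median are logged.
* **Correlations**: pairwise Pearson within group over task composites;
  partial correlations by the residual-on-controls method (OLS with
  intercept; p from t with n − 2 − k df); multiplicity adjusted per group
  (Holm by default; Bonferroni and Benjamini–Hochberg selectable).
  Independent correlations are compared by the Fisher-z statistic
  (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)).
* **Effect sizes**: Hedges-corrected standardized mean differences
  (g* = d · (1 − 3/(4·df − 1)), pooled SD); Welch tests (fractional df)
  for two-sample comparisons.
* **Error bars**: Cousineau-normalized (participant-mean centered, grand
  mean restored) per-condition SEs with the √(M/(M−1)) Morey correction;
  M = 1 falls back to the ordinary SE with a warning.

### Numerical choices

Linear mixed models are fit by REML with lbfgs (bfgs, then cg, only if
lbfgs *raises*); fixed-effect p-values use the Wald normal approximation —
a deliberate simplification of finite-sample df corrections whose adequacy
at ~100 participants is confirmed empirically by the type-I simulations.
A fit is accepted when the optimizer converges with all random-effect
variances above 10⁻⁸ × residual; otherwise the fallback ladder drops the
modality slope, then the domain slope, deterministically. When a failed
rung estimates slope variances below 10⁻³ × residual, later rungs still
containing those components are skipped, since they stall on the same flat
boundary; the final rung is always accepted as-is with its convergence and
singularity flags set. Tiny median-split subgroups whose design matrix
degenerates (e.g. a constant covariate) yield a warning and a missing
subgroup fit rather than an error.

## Problem sizes in the test suite

Simulation-based checks run at the study scale of 50 TD / 55 ASD
participants: 200 replicate cohorts for recovery of a planted TD-only
linguistic slope advantage (planted at −0.03 z/occurrence, a magnitude
chosen by power analysis to be reliably detectable at this sample size),
300 null cohorts for type-I calibration of the composite group × domain
interaction, 200 participants for slope-recovery correlations, and 1000
random fixtures for the OLS slope oracle. Slope recovery is evaluated on
the 48-target auditory design with latency noise only (false alarms and
anticipations off), isolating the estimation channel; a softer check under
the full behavioral defaults is asserted separately.

## Known limitations

* No frequentist GLMM backend is available, so the logistic model's
  variational posterior SDs can be mildly optimistic; group-level
  conclusions in the package's own simulations are insensitive to this.
* The RT model omits df corrections (see above) and models order linearly,
  matching the estimand but not saturating possible nonlinear learning
  curves.
* Exclusion percentages and exact coefficient values from any particular
  real dataset depend on details (factor coding, optimizer, data edits)
  this package fixes by its own documented conventions.
* The simulator's missing-task mechanism is completely at random; real
  dropout may be informative.
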