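# Methods

## Choice model

Choices between a safe lottery (amount `a` with probability `P`, with
`0.5 < P <= 0.8`) and a risky lottery (larger amount `A` with probability
`1 - P`) follow a softmax on the expected-utility difference,
`p_safe = logistic(beta * dEU)` with `dEU = P*U(a) - (1-P)*U(A)`.
Utility is a sign-preserving power function `U(x) = sign(x) |x|^u`: for
`u < 1` this is concave over gains (risk aversion) and convex over losses
(risk seeking), so a single curvature parameter reproduces the standard
reflection of risk attitudes across frames while keeping the inversion for
`A` well-defined for negative amounts.  Probability weighting is deliberately
omitted: all probabilities lie in the middle range (0.2–0.8) where weighting
functions are approximately linear.  Choices are coded 1 = safe, 0 = risky
throughout.

Parameters are estimated per subject by MAP under independent Gaussian
priors (defaults beta ~ N(3, 10^2), u ~ N(1, 10^2) — wide and effectively
unbiased), optimised on the natural scale with box constraints
(`beta in [1e-3, 50]`, `u in [0.05, 5]`) from a fixed 5x5 multi-start grid,
so fits are deterministic.  The posterior is summarised by a Laplace
(Gaussian) approximation with covariance equal to the inverse Hessian of the
negative log joint at the mode (finite differences of the analytic
gradient); when the Hessian is not positive definite the covariance is
flagged unavailable and the point estimate still returned.  This MAP+Laplace
scheme is a deliberate simplification of a full variational treatment; only
point estimates feed the downstream analyses.

## Stimulus design by model inversion

Fixing `(P, a)` and a target safe-choice probability `p_s`, the risky amount
solves `U(A) = (P*U(a) - logit(p_s)/beta) / (1-P)`; substituting back
reproduces the target to better than 1e-10.  Note the minus sign: the
bracketed term must *reduce* the risky option's utility when the target
favours the safe option.  A rendering of this inversion with a plus sign
looks similar but actually yields `1 - p_s` — an easy sign slip, which the
round-trip property test guards against.

Stimulus sets draw `P` uniformly from {0.55, 0.60, 0.65, 0.70, 0.75, 0.80}
and |a| uniformly from [2, 10] currency units (matching displayed exemplars
such as 65%/6.95 vs 35%/9.15), round amounts to 0.05, and reject-and-resample
pairs with `|A| <= |a|` or `|A| > 60`.  Because every accepted pair hits its
target exactly, rejection cannot bias the set mean: with a constant target
the mean model-implied `p_safe` equals the group target (70% safe-default,
30% risky-default) exactly before rounding, and within ±0.003 after currency
rounding.  Loss-frame sets use negative amounts with the same machinery; a
gain set at target `t` is the exact sign-mirror of the loss set at `1 - t`.

Per-trial target jitter (Gaussian, truncated to (0.05, 0.95)) is available
for designs that need varying difficulty.  The parameter-recovery
simulations use jitter SD 0.2 around a 0.5 target: a constant target makes
`dEU` constant across trials and hence `(beta, u)` jointly unidentifiable,
so spread in the per-trial targets is a design requirement, not a tuning
knob.

## Synthetic experiments

The simulator reproduces the study design: per group (safe-default /
risky-default), each subject completes 72 self-paced priming trials followed
by 18 blocks of 18 trials.  Blocks are grouped into three time-on-task
stages; each stage contains exactly two blocks of each time-pressure level,
with TP order rotated by a Latin square across subjects.  TP and ToT enter
all analyses as cardinal codes -1/0/+1.

Generative hypotheses (effect sizes are package defaults chosen to produce
clearly signed, plausibly sized effects; the literature constrains their
signs, not magnitudes):

* **none** — pure softmax-EU choice.
* **natural** — an additive bias `0.5 * tp_code * frame_sign` on the softmax
  input (toward safe in gains, risky in losses).
* **dominant** — an additive bias `0.5 * tp_code` toward the subject's own
  running-majority option (the default is one's own habitual choice, not a
  property of the stimuli; ties or empty history fall back to plain
  softmax).
* **learned** — a dual-process mixture: with probability
  `m(ToT) = clip(0.2 + 0.2*tot_code, 0, 1)` (0 / 0.2 / 0.4 across stages) a
  fast default process emits the running-majority option; otherwise the
  deliberative softmax decides.  TP never affects `m`.

RTs are shifted lognormals, one per process — deliberative: shift 200 ms,
meanlog 6.6, sdlog 0.5; default: shift 150 ms, meanlog 5.9, sdlog 0.35 —
spanning the plausible 300–3000 ms range.  The deliberative meanlog drops by
0.25 per TP unit, so mean RT decreases under time pressure in every scenario
(the manipulation check).  No empirical RT model is implied; the family was
chosen for right-skew and a positive lower bound.  Two consequences matter
for the fixed-point analyses: (i) under `learned`, each ToT stage's RT
distribution is by construction a binary mixture of two fixed base
distributions (TP shifts the deliberative base, but TP levels are balanced
within every stage, so the stage-pooled bases are identical across stages) —
a true fixed point across ToT; (ii) under the single-process scenarios TP
shifts the one distribution, so no fixed point exists across TP.

Choices in the priming session use tp_code = 0 and tot_code = -1; with the
default `m(-1) = 0` the priming session is purely deliberative and serves to
establish each group's majority from trial one.

Simulated cohorts share one master seed with per-subject substreams, so
tables are byte-identical under a fixed seed.  The simulator omits real-data
features it does not model: between-subject parameter heterogeneity, lapses,
fatigue, feedback effects, and any RT-choice dependence beyond the process
mixture.  Passing tests therefore validate the machinery and its directional
logic, not quantitative fits to human data.

## Choice analyses

Priming manipulation checks are one-sample t-tests of per-subject safe
proportions against 0.5, one-sided in each group's designed direction (the
reported p-values in this literature match one-sided tails).

The mixed logistic regression (choice ~ TP*ToT*CP fixed effects; random
intercept + TP + ToT slopes per subject, uncorrelated) is implemented
in-package: no installed Python library offers a likelihood-based logistic
GLMM, so the marginal likelihood integrates random effects by a Laplace
approximation around per-subject posterior modes (batched damped Newton),
and L-BFGS-B optimises fixed effects and random-effect SDs — the same
approximation lme4's `glmer` uses at `nAGQ = 1`, and the two agree to ~3
decimal places on test problems (coefficients, SEs, and log-likelihood).
Random-effect SDs are parameterised linearly with a bound at zero
(log-parameterisation creates an unbounded flat ridge as the SD collapses);
a restart-polish guards against premature termination on that ridge.  CP is
coded +1 (safe-default) / -1 (risky-default).

Backward selection starts from the full factorial, repeatedly removes the
least significant removable term (largest Wald p; a term is removable only
if no retained interaction contains it; ties broken toward higher order,
then lexicographically), and accepts each removal only if the
likelihood-ratio test against the richer model is non-significant at
alpha = 0.05 (configurable).  A significant LRT vetoes the removal and stops
the procedure.  Reduced models warm-start from the parent fit.

Calibration of this procedure needs care.  By construction it retains
whichever term happens to test significant, so under a global null the
probability that the *final model is not intercept-plus-CP* is approximately
`1 - (1-alpha)^7 ≈ 0.30` — that is a property of backward elimination
itself, not an implementation flaw.  Moreover, a retained interaction drags
its (possibly non-significant) main effects along through the hierarchy
rule.  The calibrated quantity — verified at 1.5x nominal alpha per term
over 200 null simulations — is the rate at which a given TP/ToT term ends
up retained *and* Wald-significant in the final model, i.e. the type-I rate
of the conclusions a reader would draw.

The RT manipulation check is a linear mixed model (ML) of RT on TP (+ ToT,
CP) with the same random-effects structure, delegated to statsmodels
MixedLM; RTs are fitted in seconds for optimizer conditioning and reported
in ms.

## Fixed-point test

Step 1: per participant and condition, a Gaussian KDE with kernel SD set to
the SD of that participant's RTs pooled across the factor's conditions,
evaluated on a common 512-point grid spanning [min - 3bw, max + 3bw] of the
pooled sample.  Participants need at least 5 RTs per condition; exclusions
carry logged reasons.  Step 2: for each of the three condition pairs,
crossings are sign changes of the density difference refined by linear
interpolation.  When several exist (KDE wiggle), candidates inside the
interval between the two condition medians are preferred and the
highest-density one among them returned; if none fall inside, the crossing
nearest the interval is used — the theoretically meaningful crossing can sit
in a deep inter-mode valley where a maximum-density rule would favour
spurious tail wiggles.  Step 3: a one-way repeated-measures comparison of
crossing RTs across the three pairs, scored by the BIC approximation to the
Bayes factor, `BF01 = exp((BIC_effect - BIC_null)/2)` with OLS models
`crossing ~ subject` vs `crossing ~ subject + pair` (unit-information
prior).  BF01 > 1 favours one common crossing population.  RTs are pooled
within condition regardless of the choice made.  Because the underlying
Bayesian ANOVA variant is approximated, BF magnitudes are comparable in
direction, not value.

On simulated data the test behaves as the theory demands: learned-default
experiments at the full design size yield BF01 > 1 across ToT stages in
~95% of replicates, while natural-default experiments yield BF01 < 1 across
TP levels in ~100% — and a pure shift family (the negative control) produces
systematically different pairwise crossings at the pairwise midpoints.

## Problem sizes

Test and script workloads are sized for a laptop-class single core: the
recovery simulation uses 40 subjects x 216 trials; fixed-point direction
rates use 50 replicate experiments at the full design (36 subjects, 396
trials each); null calibration of backward selection uses 200 scaled
experiments (24 subjects, 9 blocks x 9 trials plus 18 priming trials) —
scaling chosen to keep each selection under ~2 s while preserving the 3x3
within-subject balance.

## Known limitations

* Group-level (hierarchical) estimation, probability weighting, loss
  aversion, and sequential-sampling RT models are out of scope.
* The mixed logistic model uses uncorrelated random effects; correlated
  structures would need a Cholesky parameterisation.
* Wald/LRT inference carries the usual small-sample anticonservatism of
  GLMMs (no Satterthwaite correction); calibration checks quantify it.
* The fixed-point Bayes factor uses the BIC approximation; it is not a
  default-prior Bayesian ANOVA.
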