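# Methods

## Games, shifts, and categories

A symmetric 2×2 game is stored as its four role-labelled outcomes
{T, R, P, S}; the game type is the strict rank ordering (Prisoner's
Dilemma T > R > P > S; Stag Hunt R > T > P > S; Chicken T > R > S > P).
Because subtracting a constant from all four payoffs never changes ranks,
a *series* of rank-equivalent matrices is built as
`stake_multiplier · base − shift` and each member is classified into one
of five sign categories by counting negative payoffs (C1 none … C5 all).
Classification uses rank positions, not role labels, so it transfers
unchanged to games whose orderings differ. Zero payoffs count as gains
(the non-negative branch of the value function), which makes the
categories total at the boundary.

The canonical bases are PD (7,5,3,2), Stag Hunt with T and R swapped,
Chicken with P and S swapped — the same payoff multiset in all three —
and the canonical shifts (0, 3, 4, 6, 10) visit C1…C5 in order. The
exact matrix sets used in the original experiments are not transcribed
here; the canonical series is the package's stand-in, and all
category-level claims are invariant to that choice (they depend only on
sign patterns, not particular values). For iterated designs of n
matrices, shifts are placed evenly inside each category's shift interval
with the counts split across categories as evenly as n allows. Stake is
a positive multiplier applied to the base with shifts scaled along, so
category membership is stake-invariant; the default stake ladder
(1, 2, 4, 8) spans the 8× range geometrically, a choice the package
makes where only the endpoint ratio is fixed.

## The choice model

Payoffs map to subjective value through the piecewise-linear
`v(x) = x (x ≥ 0); λx − b (x < 0)`. λ is the loss-aversion slope
(reference value 2, the conventional population estimate); b the
loss-avoidance intercept (reference value 4, roughly half the span of
the canonical base). Both branches are linear: empirically estimated
curvature exponents (≈0.88–0.92) are close enough to 1 over these payoff
ranges that curvature changes none of the category-level orderings, and
keeping the branches linear makes the two asymmetries exactly additive
in u(C) − u(D) — a property the tests assert.

Expected utilities are u(C) = p·v(R) + (1−p)·v(S) and
u(D) = p·v(T) + (1−p)·v(P) with p the expectation that the partner
cooperates (default 0.5). Choice is logistic:
`P(C) = σ(β(Δu − δ₀))`, β = 1. The offset δ₀ is calibrated *once*, on
the all-gain PD base with identity utility (δ₀ = −1.5 for the canonical
base), so the neutral PD predicts exactly 50 % cooperation; the same
offset is reused for Stag Hunt and Chicken, which therefore predict
higher baseline cooperation (88 % and 73 % on the canonical bases).
The condition in the piecewise definition is read on the *input* payoff
(the only reading under which the function is well-defined).

With λ = 1 the category effects have a closed form used as the test
oracle: the shift in Δu relative to the all-gain baseline is 0 for
C1/C3/C5 (both options penalized equally), −(1−p)b for C2 and −pb for
C4 in the PD, with the C4 sign flipped in Stag Hunt (+pb) and the C2
sign flipped in Chicken (+(1−p)b) because the lone negative payoff sits
on the other option's side in those orderings. At p = 0 or 1 the
C2/C4 effects vanish — mixed outcomes are required for the asymmetry to
matter — and the package asserts this degenerate case rather than
excluding it. Per-category predictions aggregate matrices by unweighted
mean (no aggregation rule is canonical; with one matrix per category in
the canonical series the choice is moot).

## Synthetic experiments

The one-shot generator assigns `5·n` participants to categories in exact
balance, keeps a participant's category fixed across games (as in the
multi-game one-shot studies), draws each choice as Bernoulli from the
model, and reports a 0–100 expectation rating as truncated rounded
normal noise (SD 10 by default) around 100·p — the scale endpoints are
the only constrained feature, so Gaussian noise is the minimal choice.
The iterated generator builds groups of six playing full round-robin;
within an interaction the matrix order is randomized, repetitions are
consecutive, and row/column roles are fixed per interaction. Designs
(12, 5) and (20, 3) both give 5 · n_matrices · n_repetitions = 300
decisions per participant, matching the two deployed lab designs.

Reciprocity is a probabilistic Tit-for-Tat mixture: from round 2 onward
an agent copies the partner's previous move with probability w and
otherwise chooses from the model. The empirical regularity this mirrors
is a pooled ≈79 % match-previous-move share; no generative rule is
documented, and the mixture is the simplest mechanism that reproduces
any target share (a bisection calibrator finds w for a given target;
the match rate is provably monotone in w, asserted by simulation).
Population heterogeneity is a single participant-level normal random
intercept on the log-odds scale (`intercept_sd`), enough to exercise
mixed models; richer parameter heterogeneity is not modelled.
Invalid-response behaviour is injected post hoc as independent
per-trial flags at a per-participant rate, which is all the exclusion
logic observes.

What the generator does *not* emulate: reaction times, dropout,
belief updating beyond one-step copying, order/learning effects across
an iterated session, and any systematic round-1 peculiarity. Passing
tests therefore certify the analysis pipeline and the internal
consistency of model and inference at realistic sample sizes — not that
human data obey the generative model.

## Statistical battery

Per-participant category cooperation rates use valid trials only; empty
cells surface as missing values. Contrasts per game: PD — C2∪C4 vs
C1∪C3∪C5 (loss avoidance) and C1 vs C5 (loss aversion); Stag Hunt — C4
vs C2, C4 vs C135, C135 vs C2, and C3 vs C1∪C5; Chicken — the same with
the C2/C4 roles exchanged and the C3 contrast expected in the opposite
direction (λ > 1 predicts C3 *lowest* in Stag Hunt but *highest* in
Chicken; the package follows that sign flip throughout). Iterated
designs use two-sided paired t tests on per-participant pooled side
rates with the d_av effect size (mean difference over the average of
the two condition SDs — the only convention consistent with the
published effect sizes this package re-derives); one-shot designs use
Pearson chi-squared on pooled counts *without* continuity correction —
anchored by reconstructing a published 2×2 table from its printed
percentages and matching the published statistic to two decimals — with
φ = √(χ²/N) and a seeded bias-corrected bootstrap CI (the original CI
method is unstated; bias-corrected percentile over binomial resamples
of both margins, 10⁴ draws by default, is this package's choice).

`reconstruct_counts` inverts printed percentages to integer tables by
exhaustive search over all splits and counts consistent with the
printed rounding; it returns the unique solution or raises explicitly
on ambiguity or infeasibility, never silently picking. Where single
contrasts are ambiguous at integer precision, the joint system of
contrast Ns across a game's battery usually pins the table.

The stake analysis is a two-way within-subject ANOVA
(4 stake levels × 2 avoidance sides) via pingouin, reporting
Greenhouse-Geisser sphericity corrections alongside uncorrected p
values. Predictor codings for regressions: loss avoidance is
game-specific (PD: +0.6 for C2/C4, −0.4 otherwise — zero-sum over a
balanced design and exactly orthogonal to the linear trend; SH: C4 = +1,
C2 = −1, else 0; CH mirrored), loss aversion is the centered linear
trend (−2…+2) over C1…C5, expectation is mean-centered, and the
partner's previous move is ±0.5. Note the SH/CH avoidance codings are
*not* orthogonal to the linear trend over balanced cells (their dot
product is 2); only the PD coding is, and the orthogonality test is
scoped accordingly. The expectation rating is a post-treatment variable
(it responds to the assigned category), so it is available as a
predictor but excluded from headline fits by default.

Fixed-effect logistic fits use statsmodels maximum likelihood with Wald
tests; separation (including constant outcomes) raises an error rather
than being regularized away. The nested mixed logistic model
(random intercepts for participant within group within experiment) is
fitted by Laplace-approximated maximum likelihood through lme4::glmer
via `Rscript`, with explicit nested factor labels; grouping factors
with fewer than two levels are dropped, and singular fits and
convergence messages are propagated on the result object. Mixed-model
intervals are Wald 95 % bounds. GLMM point estimates are
optimizer-sensitive across implementations, so cross-implementation
comparisons should be made on sign and significance, not coefficients
to three decimals.

## Exclusions and reproduction

Iterated designs exclude participants with *more than* 10 % invalid
trials (exactly 10 % is kept — the boundary the tests pin), then drop
the remaining invalid trials; one-shot designs exclude on a single
comprehension-test error. The exclusion log accounts for every dropped
row. The reproduction driver maps a deposited long-format CSV onto the
canonical schema through a declarative adapter, applies exclusions,
runs the per-experiment battery and the pooled nested mixed model, and
emits a side-by-side table of computed versus published statistics; a
synthetic fixture in the canonical schema exercises the whole path
offline, so no download is ever required by the test suite.

## Problem sizes and numerical choices

Monte-Carlo checks run at the deployed scales: 120 participants per
category for one-shot power/false-positive rates (200 replicates),
4–8 six-person groups for iterated properties, and 8 groups × 300
trials for mixed-model variance recovery — sizes chosen so each claim
is measured at realistic n while the whole suite stays interactive.
Analytic oracle comparisons use absolute tolerance 1e−12; stochastic
assertions use 3-SE binomial bands around their targets. Ties in payoff
orderings are rejected (strictness is part of the game definition), and
property tests keep payoffs well separated so floating-point shifts
cannot manufacture ties.

## Known limitations

No utility curvature (exponents), no per-individual parameter fitting,
no Bayes factors, no Social-Value-Orientation measures, and no
modelling of payment/incentive bookkeeping. The canonical matrix series
stands in for the original stimulus tables; analyses that depend only
on categories are unaffected, but matrix-level quantities (e.g. exact
predicted rates) would differ under the original stimuli.
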