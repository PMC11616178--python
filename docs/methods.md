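# Methods

## Background and scope

`ctxbind` re-implements, as a reusable pipeline, the analysis of how a
task-irrelevant *contextual* stimulus is integrated into a stimulus–response
(S–R) episode. The experimental vehicle is the auditory four-alternative
negative-priming task: each trial consists of a *prime* and a *probe*
presentation, each pairing a target sound with a to-be-ignored distractor
sound (four environmental sounds — frog, piano, drum, bell — each mapped to
one response key, F/V/J/N). A task-irrelevant sine tone (the context)
accompanies both presentations and may repeat or change between prime and
probe. In *ignored repetition* (IR) trials the prime distractor returns as
the probe target; *control* (C) trials contain no prime–probe stimulus
repetition. Attended-repetition trials and their controls exist only to keep
participants from anticipating "no response repetition"; they are generated
for design fidelity but never analyzed.

The scientific question is whether the context enters the episode at all,
and if so how: not at all (*no integration*), as part of a compound with the
distractor that gates retrieval of the prime response (*configural
binding*), or directly bound to the response so that repeating the context
alone retrieves the prime response (*binary binding*). Inter-trial context
variability is the manipulated factor, via five between-participant groups
(blocked, ordered, disordered, mixed, random).

## Trial-schedule construction

**Tones and pairs.** The context inventory is eight sine tones, labels 1–8
with frequencies 150, 300, 400, 500, 600, 700, 800, 900 Hz. Pairs combine
tones of equal label parity; all such pairs are at least 200 Hz apart, which
is asserted (a closer pair signals a corrupted inventory). This yields
exactly 12 pairs with each tone in 3 of them. Each pair has four prime/probe
combinations (2 repetitions, 2 changes). Note that a *repetition*
combination (tone x at prime and probe) is physically shared by the three
pairs containing x; balance statements are over pair–combination slots.

**Basic set.** 48 trials: 12 IR trials and their 12 parallel controls
(prime distractor replaced by the remaining fourth sound), 12
attended-repetition trials and their 12 parallel controls (prime target
replaced). Since every no-repetition configuration would arise once as an
IR-control and once as an AR-control, the 24 IR and 24 AR triples are split
into two complementary sets (set 1 / set 2) inside which no control
configuration repeats. The split is deterministic (first half of the
lexicographic triple enumeration seeds set 1; the AR membership follows
from the complement of the used control configurations). Participants
alternate sets by participant-index parity (configurable), a deterministic
stand-in for random assignment.

**Schedules.** The basic set is implemented eight times (384 trials, 8
blocks × 48). Context assignment by group:

- *blocked* — one combination of a designated pair per block; each of the
  four combinations fills exactly two blocks, in an order drawn from the
  schedule seed (the source design does not state the order). Blocks are
  independently shuffled copies of the basic set.
- *ordered* — the designated pair's four combinations cycle in the fixed
  canonical order (a,a), (a,b), (b,a), (b,b); the cycle is identical for
  all participants. Only "a fixed order" is specified upstream; fixing the
  canonical order for everyone is the simplest reproducible reading.
- *disordered* — the four combinations in random order, exactly balanced at
  96 each (stratified shuffle, not i.i.d. draws, so the printed counts are
  deterministic).
- *mixed* — per block, exactly 36 trials (75%) follow the disordered regime
  on the designated pair and 12 (25%) follow the random regime. The random
  regime may redraw the designated pair; excluding it is not stated
  anywhere, and including it keeps the regime genuinely uniform. The split
  is enforced per block so the printed proportion holds at every scale;
  positions are randomized within block.
- *random* — draws over all 12 pairs' 48 combination slots, exactly
  balanced at 8 occurrences per slot, giving uniform exposure to all eight
  tones and 192 repetitions / 192 changes.

Every schedule satisfies: 384 trials, 96 per trial type, 192/192
context-repeated/changed, prime-target side a fair coin per trial with the
probe target on the opposite side, and full reproducibility from
(group, seed).

## The MPT model

Probe responses in IR and C trials fall into four categories: correct
(probe target), probe-distractor confusion, prime-response intrusion, and
the remaining fourth option. One processing tree per condition with
sequential branching ci → psc → prr gives

    p1 = ci
    p2 = (1−ci)·psc
    p3 = (1−ci)(1−psc)·prr
    p4 = (1−ci)(1−psc)(1−prr)

where *ci* is correct identification, *psc* probe-stimulus confusion, and
*prr* prime-response retrieval — the conditional probability of committing
the prime's response given neither a correct nor a distractor response.
The branch order follows the enumerated category list; if the true
published topology ordered the latent stages differently, saturated fits
and the prr-difference tests would be unchanged in fit but point estimates
of psc/prr would take different values. This is documented rather than
guessed further.

**Estimation.** The multinomial likelihood factorizes stage-wise into three
binomials, so saturated MLEs are closed form (ci = n1/N, psc = n2/(N−n1),
prr = n3/(n3+n4)); 0/0 ratios are reported as NaN with an `undefined` flag,
never silently as numbers. Equality restrictions on a single parameter
across trees pool the corresponding stage counts, which is the exact
constrained MLE. Counts are pooled over participants within a group before
fitting (aggregate-data MPT), matching the single per-group statistics the
battery reports; no hierarchical/latent-trait extension is attempted.

**Interaction (equal-difference) fit.** The configural-binding test
reparameterizes prr_IR = prr_C + d within each context relation and equates
d across relations. Only the third stage is constrained, so the fit
maximizes four stage-3 binomial log-likelihoods over (prr_C,rep, prr_C,chg,
d) subject to all implied probabilities in [0, 1]. Numerics: SLSQP with
analytic gradient, box bounds and coupling constraints at ε = 1e−9 from the
boundary, ftol 1e−12, and three fixed starts (saturated-based, pooled, and
centered); the best optimum is kept and a non-converged flag is reported
rather than silently returned. The additive-difference construction is this
package's choice of reparameterization; order-constraint methods from the
wider MPT literature would test the same null here.

**Inference.** G² = 2(ll_saturated − ll_restricted), df = number of
independent constraints, p from the χ² distribution, ω = √(G²/N). N is the
total count over all trees of the tested model (both trees for two-tree
tests, the joint model's four trees for group-level tests), following the
aggregate-N convention of common MPT software; this is an assumption, since
the per-test N is rarely printed.

## Test battery and classification

Per group with trees {IR, C} × {repeated, changed}:

1. **Distractor binding** (10 tests: 2 relations × 5 groups): prr_IR =
   prr_C within a relation, df = 1.
2. **Binary context binding** (5 tests): prr_C,rep = prr_C,chg within the
   joint model, df = 1.
3. **Configural context binding** (5 tests): the interaction test above,
   df = 1.

Holm (step-down Bonferroni) correction is applied within each stage's
family (10/5/5), not across all 20 tests pooled — the upstream report
corrects "multiple comparisons" per family without specifying grouping, and
per-stage families keep the three questions separate. α = 0.05 throughout.
Classification per group from adjusted flags: *binary* if stage 2 is
significant, *configural* if stage 3 is significant and stage 2 is not,
*both* if both, *none* otherwise.

**Filtering and exclusion.** Responses faster than 100 ms or slower than
3000 ms are invalid; the window is applied to both prime and probe RTs with
inclusive boundaries. A participant is excluded when the probe error rate
exceeds 0.50 (strictly) in at least one Trial Type × Context Relation cell
— "several experimental conditions" is operationalized as "at least one
within-subject cell", the most conservative reading; the threshold and rule
are configurable and the report lists all cell rates, flagging empty cells
rather than dropping them. Probe trials with an incorrect prime response
are excluded from tabulation by default (standard practice in
prime-response-retrieval analyses, configurable and logged). Descriptive
negative-priming statistics (mean correct-probe RT and error rate per
condition, IR−C differences) are computed without any F-tests.

## Synthetic data generator

The generator emulates: the 2×2×5 design, probe categories drawn from
condition-specific MPT probabilities, the five context schedules, prime
accuracy as an independent Bernoulli (default 0.90, in the vicinity of the
~0.84 average probe accuracy reported upstream; prime errors do not alter
probe category probabilities), and lognormal RTs (mean 900 ms, σ_log 0.3)
with a +50 ms shift on IR probes echoing the published ~49 ms
negative-priming effect — a free parameter, not a claim.

Preset magnitudes (all synthetic; nothing upstream prints true values):
ci = 0.80, psc = 0.25 everywhere; baseline binding gap prr_IR − prr_C =
0.15 over prr_C = 0.30; *configural* adds +0.15 to the gap under context
repetition; *binary* adds +0.12 to prr_C under repetition. These
qualitatively match the published ordering of prr estimates without
asserting unprinted numbers.

What the generator does **not** emulate: attention/saliency dynamics,
sequential (block, fatigue, learning) effects, participant heterogeneity in
the MPT parameters, attended-repetition-specific effects (those trials are
drawn from control parameters), or speed–accuracy coupling between RTs and
categories. Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to violations
found in real data.

## Verification and known limitations

- Closed-form fits are cross-checked against generic numeric maximizers
  (Nelder-Mead on the multinomial likelihood) and the interaction fit
  against a dense profile grid search; the worked two-tree example
  (40,10,30,20)/(40,10,10,40) has pooled prr = 0.40 and G²(1) ≈ 17.261.
- Null calibration: at 200 observations per tree, the df = 1 prr-equality
  test and the interaction test both reject at ≈5.4% at α = 0.05
  (10,000 / 5,000 replicates in the test suite) — within sampling error of
  nominal.
- Parameter recovery at the design scale (one group, 48 participants × 384
  trials) is unbiased (|mean error| < 0.01 on every prr), but per-replicate
  precision is limited by the stage-3 information: each tree receives about
  N·(1−ci)(1−psc)·prime_accuracy ≈ 311 stage-3 observations, so
  SE(prr̂) ≈ 0.028 and a single replicate lands within ±0.03 on all four
  prr values only ~30–45% of the time. Likewise the df = 1 tests at effect
  sizes Δprr = 0.12–0.15 have power ≈ 0.8–0.9, so single-study pattern
  classification is right in roughly 75–90% of replicates depending on the
  preset. These are properties of the design size, not of the estimator;
  the corresponding acceptance tests document them.
- Problem sizes used by the bundled experiments: calibration at 10,000 /
  5,000 replicates (tests) or 4,000 / 1,500 (acceptance script); recovery
  at 200 replicates per preset (tests) or 40 (script); the full synthetic
  study at the design's 240 participants.
- G² with observed > 0 and expected = 0 would be infinite; pooled
  closed-form estimates cannot produce this configuration, and the numeric
  fit clips probabilities at ε, but degenerate all-zero tables are
  rejected with errors rather than fit.
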