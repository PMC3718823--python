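# Methods

`coged` implements the cognitive-effort-discounting measurement procedure and
its analyses as tested software: stimulus generation for the N-back task,
the adjusting-amount staircase that yields indifference points, subjective-value
and area-under-the-curve metrics for effort and delay discounting, synthetic
choice agents for closed-loop simulation, and random-intercept multilevel
models of subjective value. This note records the model assumptions, the
defaults and why they were chosen, and the numerical decisions that were
genuinely open.

## N-back stimulus lists

A list at load N is a sequence of consonants with three mutually exclusive
roles: an item is a **target** iff it equals the item exactly N positions
back; a **lure** iff it is not a target and repeats at some lag L with
1 ≤ L ≤ N+2 and L ≠ N; a **filler** otherwise. Lure lags below N count as
lures: the rule "within N+2 positions but not exactly N" is applied
literally at every lag, which is the stricter of the two possible readings
and makes filler cleanliness well defined (fillers match no prior item at
any lag ≤ N+2).

The canonical run is 64 items with 16 targets; default lure counts per level
are {1: 8, 2: 6, 3: 5, 4–6: 3}. The alphabet is the 20 uppercase English
consonants with Y excluded as ambiguous; matching is case-insensitive.
Construction is sequential with role-plan rejection sampling (cap 10,000
attempts): because an item's role depends only on its own backward matches,
placing items left-to-right under per-position constraints realises the plan
exactly, and rejection is only needed when a planned lure's copy would
coincide with its lag-N item. A brute-force recount over all lags
(`validate_stimulus_list`) is exposed as an independent oracle and is also
what the generator itself checks before returning.

Timing (1.5 s response window, 3.5 s inter-item interval) and display
properties are carried as metadata only; no real-time behaviour is
implemented.

**Scoring.** The first N positions cannot be targets and are excluded from
both scoring denominators. d′ = z(H) − z(F) with rates clamped to
[1/(2n), 1 − 1/(2n)] of their own trial counts — a standard correction the
procedure itself does not specify, chosen so perfect runs stay finite. Mean
RT is computed over correct responded trials only. Feedback is "Good job!"
iff both the target and non-target percentage scores strictly exceed 50%.

## Adjusting-amount titration

Each staircase holds the hard (or delayed) offer fixed at the base amount A
and titrates the easy (or immediate) offer: choosing the hard option raises
it by the current step, choosing the easy option lowers it, and each step is
half the previous one. Defaults are start = A/2, first adjustment = A/4,
six choices. At the canonical A = $2.00 this is the $1.00 start and $0.50
first adjustment whose sixth adjustment is $0.015625 ($0.015 at millicent
truncation); the same fractions serve as the adjusting-immediate-amount
convention for delay staircases (50%/25% of the delayed amount) and for the
$1/$5 effort bases, where no start value is documented.

All reachable amounts are A/2 ± a signed subset-sum of {A/4·2⁻ⁱ}. With
dyadic start and step these are exact binary floating-point numbers, so no
rounding error accumulates; an integer money representation was rejected
because $0.015625 is not an integer number of any decimal sub-cent unit.
The staircase is a bisection: for any deterministic threshold agent the
post-final amount is within one final step (A/128) of the true threshold,
verified exhaustively over all 2⁶ choice paths. Exact valuation ties
resolve to the easy option (configurable). No clamping is applied at the
defaults, which cannot leave [0, A]; a flag clamps to [0.01, A − 0.01] for
nonstandard parameters.

**Scheduling.** Offers are randomized and non-nested: for each choice round
k = 1..6 every (condition, base amount) pair appears once in an
independently shuffled order, so staircases interleave rather than run to
completion. Whether the original procedure reshuffled per round or reused
one global order is not documented; per-round shuffling is the default and
a flag selects the global-order variant.

## Subjective value and AUC

SV = indifference amount / base amount, the fraction of reward value
surviving the effort or delay cost. The premium demanded for the hard
option is A·(1 − SV). Discounting curves are summarised by trapezoid AUC
over an x-axis normalized to unit width, so AUC ∈ [0, 1] when all SVs are,
AUC = 1 means no discounting, and the statistic is invariant to affine
rescaling of the raw axis. Effort AUCs default to levels N = 2–4 (the
common basis across age groups); delay AUCs use days with six months =
182.5 and a year = 365 days (calendar arithmetic the source leaves
unstated).

Under this normalized convention an always-easy responder scores
0.015625/2 ≈ 0.0078 and an always-hard responder 1.984375/2 ≈ 0.992. The
published range "0.015 … to 1.0" is not reproducible under any single
convention (0.015 matches the unnormalized grid floor, 1.0 the normalized
ceiling); the discrepancy is documented here rather than patched.

The NASA-TLX composite is the unweighted mean of per-scale trapezoid AUCs
over the normalized level axis, in raw 0–21 rating units (constant ratings
of r give exactly r). A missing scale is an error, never imputed.

The amount-effect summary pairs each participant's curves at two base
amounts: per-amount mean AUC, a paired Wilcoxon signed-rank p (NaN when
all differences are zero, where the test is undefined), and per-condition
mean discounted dollar values with their decrements. Unpaired participants
are dropped with a warning.

## Synthetic agents

Agents exist to close the loop: they make the choices the staircase needs,
so recovered SV curves can be compared against the latent truth.

* Effort: true SV(N) = clamp(1 − κ·(N−1)·A^(−γ), 0, 1). The linear decline
  in load matches the observed group-mean shape; κ is the effort cost per
  load step as a fraction of the base, and γ ≥ 0 produces a magnitude
  effect (shallower discounting at larger bases) exactly when positive.
  A convex-cost variant is deliberately not a default.
* Delay: hyperbolic present value V = A/(1 + k(A)·D), with k specified per
  amount and k at $25,000 half of k at $1,000 by default, so larger rewards
  are discounted less by construction.
* Choice: deterministic value comparison at temperature τ = 0 (ties →
  easy); otherwise P(hard) = logistic((V_hard − V_easy)/τ), making τ
  interpretable as dollars of decision noise.
* Performance: d′ = d0 − δ·(N−1) + noise floored at 0; RT = rt0 +
  slope·(N−1) + noise floored at 0.2 s.

Cohort defaults place younger adults at mean κ = 0.14 (implying a mean
effort AUC near 0.72 over N = 2–4, since AUC = 1 − 2κ for the linear
curve) and older adults at κ = 0.30 (near 0.4); d′ intercept/slope pairs
(3.42, 0.59) and (3.13, 0.58) and RT levels (0.592 s / 0.785 s at N = 1)
follow the observed load-performance profiles of the two groups. NCS-like
trait scores are generated as an affine function of the true AUC plus
noise, and income bins, workload ratings, and decision-basis ratings follow
the group-level patterns the analyses need to exercise. All randomness
derives from one cohort seed through per-agent `SeedSequence` substreams.

What the generator does *not* emulate: within-session learning or fatigue,
RT distributions conditioned on stimulus role, attrition, or any coupling
between N-back accuracy and choice behaviour beyond the level means.
Passing recovery tests therefore show that the measurement and estimation
machinery is faithful, not that these parametric forms describe human
participants.

## Multilevel models

The anchored model regresses SV on d′, mean RT (seconds), and centered load
N_c = N − 2.5 (codes −1.5..1.5 for levels 1–4), with a random
participant intercept; the two-group variant adds Age (1 = older) and
Age×N_c. The reference level N = 1 has no titrated SV; when the anchor is
included those rows enter with the theoretical SV = 1.0 and the
participant's observed N = 1 performance. The anchor-free variant restricts
to N = 2–4, centers load at 3, and uses performance *ratios* to the N = 1
values as predictors; constant ratios are dropped with a warning rather
than silently absorbed into the intercept.

Estimation maximises the restricted log-likelihood over log-variances
(Nelder-Mead; per-participant Woodbury identities make each evaluation
O(n)). The estimator is implemented in-package because the heterogeneous
variant — residual variance stratified by age group, reported with a
likelihood-ratio statistic against the nested homogeneous fit — is part of
the model family; the homogeneous case is cross-checked against
`statsmodels` MixedLM in the test suite. Data fitted exactly (zero
residual) short-circuit to the least-squares solution with zero variances
instead of chasing a singular likelihood surface.

Fixed-effect t-tests use a documented within/between df split rather than a
library default: terms constant within every participant (Age, the
intercept) get J − q_between − 1 df; all other slopes get
n − J − q_within df. For 25 participants × 4 levels with three
within-participant slopes this yields 72 df; the two-group model with four
within slopes yields 146 and the Age term 48, matching the design's
decomposition. p-values are two-sided; no multiple-testing correction is
applied.

The linear-contrast ANOVA uses centered condition coordinates as weights,
F(1, N − k) with the within-cell mean square as error, and
η² = SS_contrast/SS_total; constant data return F = 0. Group comparisons
report Wilcoxon rank-sum (exact when sample sizes permit and there are no
ties) or signed-rank plus the corresponding t-test. The covariate battery
(hierarchical ΔR², income/domain regressions, logistic age prediction with
separation detection) delegates to `statsmodels` OLS/Logit.

## Session pipeline

`ExperimentConfig` presets mirror the two published designs (levels 2–6 at
$2.00, or levels 2–4 at $1/$5 plus six delays at $1,000/$25,000); the
group-specific level sets of the first design are expressed as two presets
(`exp1-ya`, `exp1-oa`) rather than one mixed run. Payment selection draws
one choice trial uniformly and pays the amount of the option actually
chosen, times the paid repetitions (default 4; the instruction "up to 10"
is a configurable ceiling, not the default). `run_pipeline` chains
simulate → titrate → value → infer, writes tidy CSVs plus a JSON manifest
with seeds, versions and SHA-256 checksums, and is byte-identical under a
fixed seed.

## Problem sizes and known limitations

Recovery simulations in the test suite and the acceptance script use 200
replicate cohorts of 25 agents for the load-slope bias check, 120
replicates of 10 for interval coverage, and cohorts of 8–20 agents for
directional checks — sizes at which the Monte-Carlo error is a small
fraction of the effects being verified. Published regression coefficients
from the human samples are not reproduction targets (the raw data are not
deposited); the package instead verifies the printed worked examples, the
design arithmetic, and parameter recovery under its own generative model.
The REML optimiser is derivative-free and can be slow for models much
larger than these designs; the df convention is a fixed design-based rule
and is not a general Satterthwaite approximation.
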