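# Methods and design notes

This note documents the models implemented in `strategaze`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was open.

## Game space

Games are symmetric 2×2 games built in an abstract payoff space and mapped
to money as `y = 10x + 30`, constrained to £0–£90.  The strategic content
is the pair of differences `d_left = x1 − x5` and `d_right = x3 − x7`, each
ranging over {−3, −1, 1, 3}; the full space crosses the 16 difference pairs
with 4 base configurations (which pair of own payoffs is held fixed while
the others are generated from the differences).  The default fixed values
(`x = 1` for the fixed slots, so quarters 1–4 fix (x1,x3), (x5,x3),
(x1,x7), (x5,x7)) are **non-canonical**: they preserve the published
structure and keep every payoff in range, and a transcribed games CSV can
override them via `games_from_frame`.  Game classification is a pure
function of the difference signs and is verified in the tests against a
brute-force best-response oracle on the money payoffs.

## Level-k

`predict_choice` is recursive: the simulated opponent's column choice is
the transpose of the level-(k−1) row prediction (legitimate because the
games are symmetric), and the player best responds to it; responses to a
guessing opponent are computed against the uniform mixture, and ties
propagate as a guess, with a guess modelled as P(top) = 0.5 throughout
(the theory's guess carries no directional content).

Lookup programs are built by the same recursion: the level-k program is the
transposed level-(k−1) program followed by a responding stage over the own
payoffs of the inferred column (both columns when the inferred choice is a
guess).  This yields 0, 4, 6-or-8 lookups at k = 0, 1, 2.  Within a stage,
lookup order is uniformly random among orders whose consecutive moves
change the row or the column but never both — for a four-payoff stage these
are the eight Hamiltonian paths on the stage's transition cycle.  The
ordering model is a package choice; nothing in the theory fixes the order
beyond the single-axis rule.

Mixture fitting maximizes the binomial likelihood of per-game top counts
over the 2-simplex (softmax reparameterization, Nelder–Mead from four
starts); a least-squares variant on aggregated proportions is exposed
because the field uses both and neither is canonical here.  When the level
predictions coincide across all supplied games the likelihood is flat in
some direction; the fit then carries an identifiability flag and a warning.

## Gaze-coupled accumulator

The simulator is a generic gaze-coupled diffusion, deliberately agnostic
among decision field theory, attentional drift diffusion and random-walk
variants: evidence for top-minus-bottom integrates in discrete steps, and
while a payoff in one row is fixated that row's payoff signal enters the
drift at weight 1 and the other row's at the gaze discount θ.  With θ = 1
the process is a plain symmetric diffusion and the simulator is checked
against the closed-form choice probability
`P(top) = 1 / (1 + exp(−2·a·μ/σ²))`.

Defaults (all configurable): dt = 10 ms, threshold a = 1.0, drift scale
0.002 evidence per unit payoff difference per step, noise sd 0.03 per step,
θ = 0.3, lognormal fixation durations with mean 290 ms and sd 100 ms,
non-decision time 300 ms.  These were chosen so simulated response times
land in the seconds range with roughly 17 fixations per game, matching the
study conditions the generator emulates.  The non-termination guard is
6000 steps (60 s): at this bound the zero-drift games censor well under
0.1% of trials (at half that bound they alone would censor about 1%).
Censored trials are flagged, with the choice read from the evidence sign.

The gaze policy during accumulation is a first-order Markov walk over the
eight AOIs — a stand-in for empirical gaze, since the accumulator framework
itself treats the gaze pattern as static.  Transition weights prefer
common transitions by a factor of 5.3 (the observed per-cell common:rare
frequency ratio) and own-payoff destinations by 1.44, which puts the
stationary own-payoff share at 1.44/2.44 ≈ 0.59, the observed own-fixation
bias.

## Process statistics

Fixations are assigned to a payoff AOI when they fall within a
100-px-radius circle of its center, boundary inclusive (the rule says
"within"; the inclusive convention is documented and tested at 99/100/101
px).  The default layout places cell centers on a 1280×1024 screen at
(427, 341), (853, 341), (427, 683), (853, 683) with the two payoffs of a
cell offset (−75, −75) and (+75, +75); the exact experimental coordinates
are unpublished, so the layout is fully configurable and its only hard
invariant is non-overlap (center distance > 2·radius).

Canonicalization inverts the counterbalancing: payoff corner, per-trial
row/column swaps, and the row/column player transpose, in that order
(generation applies the inverse chain), mapping presentation slots to
canonical payoff labels and key codes to top/bottom choices.  The label
maps are bijections for all 32 counterbalance states and the round trip is
tested exactly.

Transitions are counted between consecutive distinct-AOI gazes after
collapsing same-AOI re-fixations (a flag restores uncollapsed behaviour;
repeats never enter the 8×8 matrix either way), with unlabelled fixations
breaking the sequence.  A transition changes some subset of {payoff owner,
own action, other's action}: exactly one change is *common* (24 ordered
cells), two or more is *rare* (32).  Optional strata: trial half (middle
transition assigned to the second half), canonical choice, game.

Gaze-bias curves bin each trial's labelled fixations by fractional position
`(index + 0.5) / n` into deciles, so trials of any length spread over the
bins (a 4-fixation trial populates four of them), and report per-bin
proportions of top-row (plus own and left-column) fixations conditioned on
the trial's choice.

## Saturated transition model

The 24 common transitions form a balanced 3 × 8 cross (type × destination).
The baseline design codes the destination with ±1 dummies (own, top, left
and their products) and the type with two orthogonal contrasts:
within-cell vs between-cell as (2, −1, −1) and within-column vs within-row
as (0, +1, −1).  Orthogonality makes exp(intercept) exactly the geometric
mean of the 24 counts, and the ±1 own coding gives the own-fixation share
as `c/(c + 1/c)` for an exponentiated own coefficient `c` (1.20 → 0.59).
A ±1 within-cell coding would match the published table's "reduced by
0.83 / increased by 1/0.83" reading directly but is unbalanced (8 vs 16
rows) and not orthogonal to the intercept; the contrast coding is a
monotone reparameterization of the same saturated model.

Estimation is two-stage: an exact per-participant solve on log counts
(saturated, so fitted counts equal observed counts; zero counts get a +0.5
continuity correction and a flag), then geometric-mean aggregation across
participants, with participant-level bootstrap percentile intervals.  This
replaces a mixed-effects Poisson regression: for the saturated baseline the
point estimates are exact, and the intervals are explicitly bootstrap, not
random-effects, intervals.  The extended designs cross the baseline columns
with scaled game differences (zL = d_left/6, zR = d_right/6, product
2·zL·zR, each spanning one unit from minimum to maximum) or with
half/choice indicators, and are solved by least squares on log counts.
Rare-transition coefficients are out of scope.

## Choice models

The battery fits each trial's top/bottom choice by logistic regression
from: nothing (intercept), free attribute dummies
(`C(d_left)*C(d_right)*C(base)`, effectively one coefficient per game), the
numeric differences, per-AOI fixation counts F1–F8, per-pair transition
counts T_ij, the last fixation's row, combinations, and "improper"
single-coefficient constraints (the top-minus-bottom fixation count
difference; the between-row transition difference).  Collinear columns are
dropped by QR before fitting; complete separation (no finite MLE) falls
back to an L2-regularized fit with a flag, never a crash.

Comparison metrics: in-sample accuracy at threshold 0.5 (the headline
metric, matching field usage); BIC with the sample-size penalty at the
number of participants — a documented, swappable policy for the nesting of
choices within participants, not a reproduction of any published
correction; and Nagelkerke R², whose additivity supports the
shared/unique variance partition.  A cluster-wise k-fold cross-validated
accuracy is also provided: for many-parameter models (8–56 gaze
predictors) in-sample accuracy carries several points of overfitting
optimism, so the null-cohort check that gaze models are at chance uses the
cross-validated estimate for those models and the in-sample estimate for
the single-coefficient ones.

The last-fixation correction enters the final fixation's row alongside the
transition counts, because the between-row transition difference and the
final row are linked by an exact accounting identity (the net difference is
0 or ±1 according to where the sequence ends); corrected and uncorrected
coefficients are reported on identical observations.

## Synthetic cohorts

The generator emulates the study's data structure: 54 participants × 64
games by default, counterbalanced player axis / payoff color / payoff
corner across participants and random row/column swaps per trial, fixation
coordinates at the presentation slot center plus Gaussian jitter (sd 20 px,
keeping >99% of fixations inside their 100-px AOI), lognormal durations
with mean 290 ms, and choices from a configurable mix of agents.  The
default mix (19.5% level 0, 54.8% level 1, 25.7% level 2) is the study's
fitted mixture; accumulator agents are opt-in.  Agent types are assigned by
largest-remainder quota so the realized mixture equals the configured one.

Emulation choices: level-k agents repeat their lookup program with
re-randomized stage orders until a per-trial count target (normal, mean 17,
sd 4) is met, because theoretical programs are single-pass but empirical
trials revisit payoffs; level-0 agents, who need no payoff information,
emit uniform random AOIs at the same count target; level-k agents tremble
(choose randomly) with probability 0.05.  The null cohort is the level-0
cohort: gaze independent of choice, used to verify flat gaze-bias curves
and chance-level gaze models.

What passing tests on these cohorts do *not* show: the generator contains
no saccade dynamics, blinks, calibration drift, or measurement noise beyond
coordinate jitter; level-k fixation streams are far more regular than human
ones; and a cohort heavy in level-1 agents has a structurally higher
own-fixation share (near 1 for pure level-1) than the 0.59 of human data,
which the accumulator gaze policy, not the level-k agents, is calibrated to
match.  Recovery results therefore demonstrate the correctness of the
estimators under the stated generative assumptions, not robustness to real
eye-tracking artefacts.

## Problem sizes in the shipped checks

The test suite and examples use simulation sizes chosen to make the checked
contrasts unambiguous at comfortable margins: 10,000 choices per game for
mixture recovery at the tight (±0.02) tolerance, a full 54 × 64 cohort for
the end-to-end recovery at ±0.08, 2,000 rule draws per game for slope
recovery, 250 accumulator trials per difference pair for the signature
battery, and a 54-participant null cohort for the controls.
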