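# strategaze

Process-tracing analysis of eye movements in strategic choice: what do
people *look at* while they decide how to play a 2×2 game, and which theory
of the choice process do those eye movements support?

The package is aimed at researchers in behavioural game theory and
decision-process modelling.  It implements, as a tested and reusable
library, the full analysis chain for fixation data recorded while
participants play symmetric 2×2 games (prisoner's dilemma, stag hunt,
hawk–dove and their relatives), together with the two competing process
models the data are used to arbitrate between:

* **Level-k reasoning** — a level-k player best responds to a simulated
  level-(k−1) opponent; level 0 randomizes.  The theory predicts both
  choices and an ordered *lookup program* over the eight payoff regions.
* **Gaze-coupled evidence accumulation** — a drift-diffusion process that
  integrates the row payoff difference to a threshold, accumulating faster
  for the currently fixated row.  It predicts choices as a logit function of
  the drift, response times that peak where evidence is balanced, and a
  late gaze bias toward the chosen row.

## The models

Games are generated in a two-dimensional strategy space.  With own payoffs
$x_1, x_3, x_5, x_7$ (top-left, top-right, bottom-left, bottom-right) and
money payoffs $y_i = 10x_i + 30$ (£0–£90), a game is characterised by
$d_L = x_1 - x_5$ and $d_R = x_3 - x_7$, each in $\{-3,-1,1,3\}$: a 4×4
grid crossed with 4 base configurations gives the 64-game space.  The signs
of $(d_L, d_R)$ determine the game class.

Level-1 chooses top iff $d_L + d_R > 0$; level-2 best responds to the
simulated level-1 column choice; ties propagate as a guess.  Choice data
are fitted by a mixture over levels 0–2 with binomial maximum likelihood.

The accumulator's analytic choice rule is
$P(\text{top}) = \text{logit}^{-1}\big(\beta\,(d_L + d_R)\big)$, and the
process simulator integrates
$\Delta E = \delta\,(w_\text{top}\,V_\text{top} - w_\text{bot}\,V_\text{bot}) + \varepsilon$
per 10-ms step, where the fixated row's weight is 1 and the other row's is
the gaze discount $\theta \in [0,1]$, until $|E|$ reaches the threshold.

Process statistics follow the descriptive route: fixations are assigned to
payoff AOIs (100-px-radius circles), recoded into a canonical frame
(inverting counterbalanced player axis, payoff corner and per-trial
row/column swaps), and reduced to an 8×8 transition matrix whose 24
*common* cells (exactly one change of payoff owner, own action or other's
action) are modelled by a saturated log-linear (Poisson-style) regression.
Choices are then fitted from attributes, fixation counts, transition counts
and the last fixation by logistic models compared on accuracy,
nesting-corrected BIC and Nagelkerke $R^2$.

## Worked example

`examples/accumulator_signatures.py` simulates 200 accumulator trials per
difference pair and prints the model's signature effects:

```
drift   P(top)  mean RT (s)
  -6    0.000   1.69
  -4    0.005   2.34
  -2    0.038   4.17
  +0    0.508   9.30
  +2    0.997   4.20
  +4    1.000   2.30
  +6    1.000   1.62
-> P(top) is monotone in the drift; RT is longest at drift 0

refit logistic slope on drift: 1.870 (95% CI 1.688-2.051)
RT vs |drift| rank correlation: -0.96 (negative: balanced games are slow)

gaze bias (proportion of fixations to the top row):
  top-choosers:    first decile 0.50 -> last decile 0.64
  bottom-choosers: first decile 0.52 -> last decile 0.29
```

The three blocks are the discriminating signatures: choice probability
rises monotonically with the payoff drift; balanced games take several
times longer than decisive ones; and, conditioned on the eventual choice,
gaze drifts toward the chosen row late in the trial.  Level-k lookup
programs (`examples/levelk_predictions.py`) reproduce the choice pattern
but predict *no* late gaze bias — the contrast the test suite checks
explicitly.

Other examples: `build_games.py` (game space construction and
classification), `levelk_predictions.py` (the 16-row prediction table and
mixture recovery), `process_pipeline.py` (synthetic cohort through the full
pipeline via `strategaze.io.run_pipeline`).

## Layout

```
src/strategaze/
  games.py             game-space construction and classification
  levelk.py            level-k predictions, mixture fit, lookup simulation
  accumulator.py       gaze-coupled diffusion simulator and choice rule
  gaze.py              AOI assignment, canonicalization, transitions, curves
  transition_model.py  saturated log-linear transition model
  choicemodels.py      logistic choice-model battery and comparison metrics
  synth.py             synthetic cohort generator
  io.py                TSV/CSV schemas and the end-to-end pipeline
docs/methods.md        modelling and design notes
examples/              one narrative script per capability
```
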