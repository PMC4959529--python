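"""Signature effects of the gaze-coupled accumulator.

Simulates 200 trials per difference pair and prints the three signatures
that separate accumulator dynamics from level-k lookup programs: choice
probability rising with the payoff drift, response times peaking where the
evidence is balanced, and a late gaze bias toward the ultimately chosen row.
"""

import numpy as np

from strategaze.accumulator import AccumulatorParams, signature_battery
from strategaze.games import default_game_grid

games = [g for g in default_game_grid() if g.base_config == 1]
rng = np.random.default_rng(99)
summary = signature_battery(AccumulatorParams(), games, n_trials=200, rng=rng)

print("drift   P(top)  mean RT (s)")
pooled = summary.per_game.groupby("drift").agg(
    p_top=("p_top", "mean"), rt=("mean_rt_ms", "mean")
)
for drift, row in pooled.iterrows():
    print(f"{drift:+4d}    {row['p_top']:.3f}   {row['rt'] / 1000:.2f}")
print("-> P(top) is monotone in the drift; RT is longest at drift 0")

print(f"\nrefit logistic slope on drift: {summary.drift_slope:.3f} "
      f"(95% CI {summary.drift_slope_ci[0]:.3f}-{summary.drift_slope_ci[1]:.3f})")
print(f"RT vs |drift| rank correlation: {summary.rt_drift_rank_corr:.2f} "
      "(negative: balanced games are slow)")

top = summary.gaze_curve[summary.gaze_curve["measure"] == "top"]
first = top[top["bin"] == 0].set_index("choice")["proportion"]
last = top[top["bin"] == 9].set_index("choice")["proportion"]
print(f"\ngaze bias (proportion of fixations to the top row):")
print(f"  top-choosers:    first decile {first['top']:.2f} -> last decile {last['top']:.2f}")
print(f"  bottom-choosers: first decile {first['bottom']:.2f} -> last decile {last['bottom']:.2f}")
print("-> gaze drifts toward the chosen row late in the trial; "
      "level-k programs predict no such bias")
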