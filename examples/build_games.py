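"""Construct the 64-game symmetric 2x2 game space and classify it.

Each game is defined by two strategic differences: the payoff advantage of
the top action when the opponent plays left (d_left) and when the opponent
plays right (d_right).  The signs of the pair give the game's strategic
class (prisoner's-dilemma-like conflict, stag-hunt coordination, hawk-dove
anti-coordination, or dominance without conflict).
"""

from collections import Counter

from strategaze.games import classify_game, default_game_grid, games_to_frame

games = default_game_grid()
print(f"built {len(games)} games, "
      f"{len({(g.d_left, g.d_right) for g in games})} difference pairs, "
      f"{len({g.base_config for g in games})} base configurations")

counts = Counter(classify_game(g).value for g in games)
for label, n in sorted(counts.items()):
    print(f"  {label:28s} {n} games")
print("(16 games per class: the sign quadrants of the 4x4 difference grid)")

table = games_to_frame(games)
print(f"\npayoff range: {table[[f'y{i}' for i in range(1, 9)]].min().min():.0f}"
      f"-{table[[f'y{i}' for i in range(1, 9)]].max().max():.0f} GBP")
print(table.head(4).to_string(index=False))
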