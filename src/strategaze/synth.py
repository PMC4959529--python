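"""Synthetic cohorts emulating the study's data structure.

The generator produces fixation and choice logs in the exact TSV schemas the
analysis pipeline reads, for a cohort of participants playing the 64-game
grid.  Defaults follow the study conditions: 54 participants, 64 games each,
lognormal fixation durations with mean 290 ms, a 1280x1024 screen layout,
between-participant counterbalancing of player axis / payoff color / payoff
corner, and per-trial random row and column swaps.

Agents
------
Each participant is one agent type.  Level-1 and level-2 agents choose by
their level-k prediction (with a small tremble) and emit fixation streams by
repeating their lookup program — with re-randomized stage orders — until a
per-trial fixation-count target near the observed 17 is met (theoretical
level-k programs are single-pass; empirical trials revisit payoffs).
Level-0 agents have no lookup program, so they emit uniform random AOIs and
coin-flip choices.  Accumulator agents delegate to the gaze-coupled
diffusion simulator, which yields choices, response times and fixation
sequences jointly.

Agent types are assigned to participants by largest-remainder quota from the
mix proportions (then shuffled), so the realized mixture equals the
configured one as closely as integer counts allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accumulator import AccumulatorParams, simulate_trial, _lognormal_params
from .games import Game, default_game_grid, games_to_frame
from .gaze import CounterbalanceState, Layout, default_layout, presentation_label_map
from .levelk import predict_choice, simulate_lookups

__all__ = ["CohortConfig", "CohortData", "generate_cohort", "generate_null_cohort"]

AGENT_TYPES = ("level0", "level1", "level2", "accumulator")

FIXATION_COLUMNS = [
    "participant_id", "trial_index", "game_id", "fix_index",
    "onset_ms", "x_px", "y_px", "duration_ms",
]
CHOICE_COLUMNS = [
    "participant_id", "trial_index", "game_id", "choice", "rt_ms",
    "player_axis", "own_color", "own_corner", "row_swapped", "col_swapped",
]


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 54
    games: tuple[Game, ...] | None = None   # None -> the 64-game default grid
    agent_mix: tuple[float, float, float, float] = (0.195, 0.548, 0.257, 0.0)
    tremble: float = 0.05
    fixation_noise_sd: float = 20.0          # px jitter around AOI centers
    fixation_mean_ms: float = 290.0
    fixation_sd_ms: float = 100.0
    fixation_count_mean: float = 17.0        # per-trial target for level-k/null agents
    fixation_count_sd: float = 4.0
    nondecision_ms: float = 300.0
    layout: Layout = field(default_factory=default_layout)
    accumulator_params: AccumulatorParams = field(default_factory=AccumulatorParams)
    counterbalance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.array(self.agent_mix)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("agent_mix must be nonnegative and sum to 1")
        if not 0 <= self.tremble <= 1:
            raise ValueError("tremble must be in [0, 1]")
        self.layout.validate()

    def game_list(self) -> list[Game]:
        return list(self.games) if self.games is not None else default_game_grid()


@dataclass
class CohortData:
    fixations: pd.DataFrame
    choices: pd.DataFrame
    games: pd.DataFrame
    manifest: dict


def _agent_quota(mix: tuple[float, ...], n: int) -> list[str]:
    """Largest-remainder apportionment of n participants over agent types."""
    raw = np.array(mix) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for t, c in zip(AGENT_TYPES, counts):
        out.extend([t] * c)
    return out


_CB_CYCLE = [
    CounterbalanceState(axis, color, corner)
    for axis in ("rows", "columns")
    for color in ("green", "blue")
    for corner in ("top_left", "bottom_right")
]


def _presentation_choice(choice: str, cb: CounterbalanceState) -> str:
    top = choice == "top"
    if cb.player_axis == "rows":
        return "up" if top != cb.row_swapped else "down"
    return "left" if top != cb.col_swapped else "right"


def _levelk_labels(
    g: Game, k: int, target: int, rng: np.random.Generator
) -> list[int]:
    labels: list[int] = []
    while len(labels) < target:
        seq, _ = simulate_lookups(g, k, rng)
        labels.extend(seq)
    return labels


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate a full cohort: fixation log, choice log, games table and a
    manifest of the generating parameters.  Fully reproducible from
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    games = config.game_list()
    agents = _agent_quota(config.agent_mix, config.n_participants)
    rng.shuffle(agents)
    mu_ln, sigma_ln = _lognormal_params(config.fixation_mean_ms, config.fixation_sd_ms)

    fix_rows, choice_rows = [], []
    for p_idx in range(config.n_participants):
        pid = f"p{p_idx + 1:03d}"
        agent = agents[p_idx]
        base_cb = (_CB_CYCLE[p_idx % len(_CB_CYCLE)] if config.counterbalance
                   else CounterbalanceState())
        order = rng.permutation(len(games))
        for t_idx, g_idx in enumerate(order):
            g = games[g_idx]
            cb = CounterbalanceState(
                base_cb.player_axis, base_cb.own_color, base_cb.own_corner,
                row_swapped=bool(rng.random() < 0.5),
                col_swapped=bool(rng.random() < 0.5),
            )
            target = int(np.clip(
                round(rng.normal(config.fixation_count_mean,
                                 config.fixation_count_sd)), 4, 60,
            ))
            if agent == "accumulator":
                sim = simulate_trial(g, config.accumulator_params, rng, pid, t_idx)
                labels = [f.aoi for f in sim.fixations]
                durations = [f.duration_ms for f in sim.fixations]
                choice = sim.choice
                rt = sim.rt_ms
            else:
                if agent == "level0":
                    labels = list(rng.integers(1, 9, size=target))
                    choice = "top" if rng.random() < 0.5 else "bottom"
                else:
                    k = 1 if agent == "level1" else 2
                    labels = _levelk_labels(g, k, target, rng)
                    pred = predict_choice(g, k).action
                    if pred == "guess" or rng.random() < config.tremble:
                        choice = "top" if rng.random() < 0.5 else "bottom"
                    else:
                        choice = pred
                durations = list(rng.lognormal(mu_ln, sigma_ln, size=len(labels)))
                rt = float(sum(durations) + config.nondecision_ms)
            label_map = presentation_label_map(cb)
            onset = 0.0
            for f_idx, (lab, dur) in enumerate(zip(labels, durations)):
                slot = label_map[lab]
                cx, cy = config.layout.aoi_centers[slot]
                jitter = rng.normal(0.0, config.fixation_noise_sd, size=2)
                fix_rows.append({
                    "participant_id": pid, "trial_index": t_idx,
                    "game_id": g.game_id, "fix_index": f_idx,
                    "onset_ms": round(onset, 3),
                    "x_px": round(cx + jitter[0], 2),
                    "y_px": round(cy + jitter[1], 2),
                    "duration_ms": round(dur, 3),
                })
                onset += dur
            choice_rows.append({
                "participant_id": pid, "trial_index": t_idx, "game_id": g.game_id,
                "choice": _presentation_choice(choice, cb),
                "rt_ms": round(rt, 3),
                "player_axis": cb.player_axis, "own_color": cb.own_color,
                "own_corner": cb.own_corner,
                "row_swapped": cb.row_swapped, "col_swapped": cb.col_swapped,
            })
    manifest = {
        "generator": "strategaze.synth.generate_cohort",
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_games": len(games),
        "agent_mix": dict(zip(AGENT_TYPES, config.agent_mix)),
        "agents_assigned": {t: agents.count(t) for t in AGENT_TYPES},
        "tremble": config.tremble,
        "fixation_noise_sd": config.fixation_noise_sd,
        "fixation_mean_ms": config.fixation_mean_ms,
        "counterbalance": config.counterbalance,
    }
    return CohortData(
        fixations=pd.DataFrame(fix_rows, columns=FIXATION_COLUMNS),
        choices=pd.DataFrame(choice_rows, columns=CHOICE_COLUMNS),
        games=games_to_frame(games),
        manifest=manifest,
    )


def generate_null_cohort(config: CohortConfig) -> CohortData:
    """Null cohort: every participant emits uniform random AOIs and
    coin-flip choices (gaze independent of choice).  Used to verify flat
    gaze-bias curves and chance-level gaze-based choice models."""
    null_cfg = CohortConfig(
        **{**asdict_shallow(config), "agent_mix": (1.0, 0.0, 0.0, 0.0)}
    )
    data = generate_cohort(null_cfg)
    data.manifest["generator"] = "strategaze.synth.generate_null_cohort"
    return data


def asdict_shallow(config: CohortConfig) -> dict:
    """dataclasses.asdict without recursing into nested dataclasses."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}
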