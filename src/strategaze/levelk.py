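"""Level-k reasoning: choice predictions, mixture fitting, and the lookup
sequences the theory implies.

A level-0 player randomizes.  A level-k (k >= 1) player best responds to a
level-(k-1) opponent.  In a symmetric 2x2 game this reduces to simple sign
rules on the strategic differences: level 1 chooses top iff
``d_left + d_right > 0`` (the expected-payoff comparison against a uniform
opponent), and level 2 best responds to the column choice of a simulated
level-1 opponent.  Ties propagate as a guess.

The theory also implies a *lookup program*: an ordered series of stages, each
requiring a set of payoff regions to be inspected.  Within a stage any order
of lookups is allowed subject to single-axis transitions (eye movements that
change the row or the column, never both).  ``simulate_lookups`` samples
concrete fixation sequences from that program; ``predicted_gaze_bias`` turns
many such sequences into the decile gaze curves the theory predicts (which,
notably, show no late bias toward the chosen row).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import softmax

from .games import Game, PayoffLabel

__all__ = [
    "LevelKPrediction",
    "MixtureWeights",
    "MixtureFitResult",
    "LookupProgram",
    "TRANSPOSE_MAP",
    "predict_choice",
    "mixture_choice_probability",
    "fit_mixture",
    "lookup_program",
    "simulate_lookups",
    "predicted_transitions",
    "predicted_gaze_bias",
]

#: Relabelling that exchanges the roles of the two players in a symmetric
#: game (own<->other and row<->column simultaneously).
TRANSPOSE_MAP: dict[int, int] = {1: 2, 2: 1, 3: 6, 6: 3, 5: 4, 4: 5, 7: 8, 8: 7}


@dataclass(frozen=True)
class LevelKPrediction:
    k: int
    action: str  # "top" | "bottom" | "guess"

    def __post_init__(self) -> None:
        if self.action not in ("top", "bottom", "guess"):
            raise ValueError(f"invalid action {self.action!r}")
        if self.k == 0 and self.action != "guess":
            raise ValueError("level 0 always guesses")

    @property
    def top_score(self) -> float:
        """Probability of a top choice implied by the prediction."""
        return {"top": 1.0, "bottom": 0.0, "guess": 0.5}[self.action]


@dataclass(frozen=True)
class MixtureWeights:
    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        w = np.array([self.p0, self.p1, self.p2])
        if np.any(w < -1e-12):
            raise ValueError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2])


@dataclass(frozen=True)
class LookupProgram:
    """Ordered stages of payoff lookups; each stage is a set of labels 1-8."""

    stages: tuple[tuple[str, frozenset[int]], ...]

    @property
    def n_lookups(self) -> int:
        return sum(len(s) for _, s in self.stages)


def _best_response(g: Game, column_action: str) -> str:
    """Row best response to a column action ('left', 'right' or 'guess')."""
    if column_action == "left":
        d = g.d_left
    elif column_action == "right":
        d = g.d_right
    else:  # respond to the uniform mixture
        d = g.d_left + g.d_right
    if d > 0:
        return "top"
    if d < 0:
        return "bottom"
    return "guess"


def predict_choice(g: Game, k: int) -> LevelKPrediction:
    """Level-k choice prediction for a symmetric 2x2 game.

    Computed recursively: the simulated level-(k-1) opponent's column choice
    is the transpose of the level-(k-1) row prediction (the game is
    symmetric), and the level-k player best responds to it.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return LevelKPrediction(0, "guess")
    opponent = predict_choice(g, k - 1)
    column_action = {"top": "left", "bottom": "right", "guess": "guess"}[opponent.action]
    return LevelKPrediction(k, _best_response(g, column_action))


def mixture_choice_probability(w: MixtureWeights, g: Game) -> float:
    """P(top) under a mixture of level-0/1/2 players: sum_k p_k * s_k with
    s_k = 1, 0, 0.5 for a top, bottom or guess prediction."""
    scores = np.array([predict_choice(g, k).top_score for k in range(3)])
    return float(w.as_array() @ scores)


@dataclass(frozen=True)
class MixtureFitResult:
    weights: MixtureWeights
    loglik: float
    converged: bool
    identifiability_warning: bool
    method: str


def _prediction_matrix(games: list[Game]) -> np.ndarray:
    return np.array(
        [[predict_choice(g, k).top_score for k in range(3)] for g in games]
    )


def fit_mixture(
    top_counts: np.ndarray,
    totals: np.ndarray,
    games: list[Game],
    method: str = "ml",
) -> MixtureFitResult:
    """Estimate mixture proportions over levels 0-2 from per-game top counts.

    ``method='ml'`` (default) maximizes the binomial likelihood with
    P(top) from ``mixture_choice_probability`` over the 2-simplex (softmax
    reparameterization).  ``method='ls'`` minimizes squared error on the
    aggregated choice proportions instead.

    If the level predictions coincide across all supplied games in some
    direction, the likelihood is flat there; the result then carries an
    identifiability warning.
    """
    top_counts = np.asarray(top_counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if top_counts.shape != totals.shape or len(top_counts) != len(games):
        raise ValueError("top_counts, totals and games must align")
    S = _prediction_matrix(games)  # n_games x 3

    # flat directions: two levels predict identically on every supplied game
    degenerate = any(
        np.allclose(S[:, i], S[:, j]) for i, j in itertools.combinations(range(3), 2)
    )
    if degenerate:
        warnings.warn(
            "level predictions coincide across all supplied games; "
            "mixture weights are not separately identified",
            stacklevel=2,
        )

    def neg_loglik(theta: np.ndarray) -> float:
        w = softmax(np.concatenate([[0.0], theta]))
        p = np.clip(S @ w, 1e-10, 1 - 1e-10)
        return -float(top_counts @ np.log(p) + (totals - top_counts) @ np.log1p(-p))

    def sse(theta: np.ndarray) -> float:
        w = softmax(np.concatenate([[0.0], theta]))
        obs = np.divide(top_counts, totals, out=np.full_like(totals, 0.5),
                        where=totals > 0)
        return float(np.sum((obs - S @ w) ** 2))

    objective = neg_loglik if method == "ml" else sse
    if method not in ("ml", "ls"):
        raise ValueError("method must be 'ml' or 'ls'")

    best = None
    for start in ([0.0, 0.0], [2.0, -2.0], [-2.0, 2.0], [2.0, 2.0]):
        res = minimize(objective, np.array(start), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    w = softmax(np.concatenate([[0.0], best.x]))
    weights = MixtureWeights(*np.round(w / w.sum(), 12))
    ll = -neg_loglik(best.x)
    return MixtureFitResult(
        weights=weights,
        loglik=ll,
        converged=bool(best.success),
        identifiability_warning=degenerate,
        method=method,
    )


def _transpose_stage(labels: frozenset[int]) -> frozenset[int]:
    return frozenset(TRANSPOSE_MAP[i] for i in labels)


OWN_ALL = frozenset({1, 3, 5, 7})


def lookup_program(g: Game, k: int, *, game_specific: bool = True) -> LookupProgram:
    """The ordered stages of payoff lookups a level-k player needs.

    Stage k's program is the transpose of the level-(k-1) program (the
    player simulates the opponent's reasoning on the transposed game)
    followed by a responding stage: the player's own payoffs in the
    simulated opponent's chosen column, or in both columns when that
    simulated choice is itself a guess.

    With ``game_specific=False`` the responding stage always covers both
    columns (the game-agnostic program used for transition predictions).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return LookupProgram(stages=())
    inner = lookup_program(g, k - 1, game_specific=game_specific)
    stages = [
        (f"simulate_L{k - 1}:{lbl}", _transpose_stage(s)) for lbl, s in inner.stages
    ]
    if game_specific:
        opponent = predict_choice(g, k - 1)
        column = {"top": "left", "bottom": "right", "guess": "guess"}[opponent.action]
    else:
        column = "guess"
    respond = {
        "left": frozenset({1, 5}),
        "right": frozenset({3, 7}),
        "guess": OWN_ALL,
    }[column]
    stages.append((f"respond_L{k}", respond))
    return LookupProgram(stages=tuple(stages))


def _single_axis_pairs(labels: frozenset[int]) -> set[frozenset[int]]:
    """Unordered pairs within a stage that change the row or the column but
    not both (the transitions level-k theory allows within a stage)."""
    pairs = set()
    for a, b in itertools.combinations(sorted(labels), 2):
        la, lb = PayoffLabel(a), PayoffLabel(b)
        if (la.row == lb.row) != (la.col == lb.col):  # exactly one axis shared
            pairs.add(frozenset({a, b}))
    return pairs


def predicted_transitions(
    k: int, g: Game | None = None
) -> list[tuple[str, set[frozenset[int]]]]:
    """Allowed within-stage transitions for each stage of the level-k lookup
    program (single-axis moves among the stage's payoff set).

    Without a game, the responding stage is taken over both columns (as for
    a guessed simulated choice)."""
    if g is None:
        from .games import Game as _G  # placeholder game; only structure matters
        prog = lookup_program(_G.from_own_x(1, 1, 0, 0, base_config=1), k,
                              game_specific=False)
    else:
        prog = lookup_program(g, k, game_specific=True)
    return [(lbl, _single_axis_pairs(s)) for lbl, s in prog.stages]


def _stage_orders(labels: frozenset[int]) -> list[tuple[int, ...]]:
    """All orders of a stage's lookups whose consecutive pairs are
    single-axis moves (Hamiltonian paths in the stage's transition graph)."""
    allowed = _single_axis_pairs(labels)
    orders = []
    for perm in itertools.permutations(sorted(labels)):
        if all(frozenset(p) in allowed for p in zip(perm, perm[1:])):
            orders.append(perm)
    return orders


def simulate_lookups(
    g: Game, k: int, rng: np.random.Generator
) -> tuple[list[int], LookupProgram]:
    """Sample one fixation sequence from the level-k lookup program: each
    stage's payoffs are looked up once, in a uniformly random order among
    those consistent with single-axis within-stage transitions."""
    prog = lookup_program(g, k)
    sequence: list[int] = []
    for _, labels in prog.stages:
        if len(labels) == 1:
            sequence.extend(labels)
            continue
        orders = _stage_orders(labels)
        sequence.extend(orders[rng.integers(len(orders))])
    return sequence, prog


def predicted_gaze_bias(
    k: int,
    n_sims: int,
    rng: np.random.Generator,
    games: list[Game] | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Gaze-bias curves implied by level-k lookup sequences.

    Simulates ``n_sims`` passes over the game set, bins each sequence's
    fixations into ``n_bins`` time bins by fractional position, and returns
    the per-bin proportion of top-row fixations conditioned on the predicted
    choice (guesses resolved by a coin flip).  Columns: bin, choice,
    prop_top, n.
    """
    if k < 1:
        raise ValueError("gaze-bias prediction requires k >= 1")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if games is None:
        from .games import default_game_grid
        games = default_game_grid()
    top = np.zeros((n_bins, 2))
    n = np.zeros((n_bins, 2))
    for _ in range(n_sims):
        for g in games:
            seq, _ = simulate_lookups(g, k, rng)
            pred = predict_choice(g, k).action
            if pred == "guess":
                pred = "top" if rng.random() < 0.5 else "bottom"
            ci = 0 if pred == "top" else 1
            m = len(seq)
            for i, label in enumerate(seq):
                b = min(int((i + 0.5) / m * n_bins), n_bins - 1)
                n[b, ci] += 1
                if label <= 4:
                    top[b, ci] += 1
    rows = []
    for ci, choice in enumerate(("top", "bottom")):
        for b in range(n_bins):
            rows.append({
                "bin": b,
                "choice": choice,
                "prop_top": top[b, ci] / n[b, ci] if n[b, ci] else np.nan,
                "n": int(n[b, ci]),
            })
    return pd.DataFrame(rows)
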