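"""From raw fixations to canonical process data.

The pipeline: pixel fixations are assigned to payoff AOIs (100-px-radius
circles around the eight payoff regions), trials are recoded into a canonical
frame (the participant described as a row player with own payoffs
odd-indexed, unswapped rows/columns, own payoffs top-left in each cell), and
the resulting gaze sequences are reduced to transition tallies, gaze-bias
curves and summary statistics.

Transition taxonomy
-------------------
An ordered pair of distinct payoff labels changes some subset of three
attributes: the payoff's owner, the player's own action (row), and the other
player's action (column).  Exactly one change makes a *common* transition
(within-cell, within-column or within-row); two or more changes make a *rare*
transition.  Of the 56 ordered pairs, 24 are common and 32 rare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .games import PayoffLabel

logger = logging.getLogger(__name__)

__all__ = [
    "Layout",
    "FixationEvent",
    "CounterbalanceState",
    "TrialRecord",
    "TransitionClass",
    "TransitionTally",
    "default_layout",
    "assign_fixations",
    "presentation_label_map",
    "canonical_label_map",
    "canonicalize",
    "classify_transition",
    "transition_tally",
    "gaze_bias_curve",
    "summary_stats",
]


# ---------------------------------------------------------------------------
# layout and AOI assignment

@dataclass(frozen=True)
class Layout:
    """Screen geometry: AOI centers (pixels, origin top-left) and radius.

    Slot indices 1-8 are positional: cells (top-left, top-right,
    bottom-left, bottom-right) hold slots (1,2), (3,4), (5,6), (7,8), with
    the odd slot at the cell's top-left corner and the even slot at its
    bottom-right corner.
    """

    screen: tuple[int, int] = (1280, 1024)
    aoi_centers: dict[int, tuple[float, float]] = field(default_factory=dict)
    radius: float = 100.0

    def validate(self) -> None:
        if set(self.aoi_centers) != set(range(1, 9)):
            raise ValueError("layout must define AOI centers for slots 1-8")
        w, h = self.screen
        pts = {i: np.asarray(c, dtype=float) for i, c in self.aoi_centers.items()}
        for i, p in pts.items():
            if not (0 <= p[0] <= w and 0 <= p[1] <= h):
                raise ValueError(f"AOI {i} center {tuple(p)} off-screen")
        for i in range(1, 9):
            for j in range(i + 1, 9):
                d = np.linalg.norm(pts[i] - pts[j])
                if d <= 2 * self.radius:
                    raise ValueError(
                        f"AOIs {i} and {j} overlap (center distance {d:.1f} px "
                        f"<= {2 * self.radius:.0f})"
                    )


def default_layout() -> Layout:
    """Default 1280x1024 layout: cell centers at (427,341), (853,341),
    (427,683), (853,683); the odd slot offset (-75,-75) from its cell
    center, the even slot (+75,+75)."""
    cells = {
        (0, 0): (427.0, 341.0),
        (0, 1): (853.0, 341.0),
        (1, 0): (427.0, 683.0),
        (1, 1): (853.0, 683.0),
    }
    centers: dict[int, tuple[float, float]] = {}
    for (r, c), (cx, cy) in cells.items():
        base = 1 + 4 * r + 2 * c
        centers[base] = (cx - 75.0, cy - 75.0)
        centers[base + 1] = (cx + 75.0, cy + 75.0)
    return Layout(aoi_centers=centers)


@dataclass(frozen=True)
class FixationEvent:
    """A single fixation: onset and duration in ms, position in screen
    pixels, and (after assignment) a payoff AOI label 1-8 or None."""

    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float
    aoi: int | None = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("fixation duration must be positive")


def assign_fixations(
    events: Sequence[FixationEvent], layout: Layout
) -> list[FixationEvent]:
    """Label each fixation with the AOI whose center lies within the layout
    radius (boundary inclusive: distance <= radius counts as inside), or
    None.  Non-overlapping AOIs guarantee at most one candidate."""
    layout.validate()
    slots = sorted(layout.aoi_centers)
    centers = np.array([layout.aoi_centers[i] for i in slots])
    out = []
    for ev in events:
        d = np.linalg.norm(centers - np.array([ev.x_px, ev.y_px]), axis=1)
        hits = np.flatnonzero(d <= layout.radius)
        aoi = slots[hits[0]] if hits.size else None
        out.append(replace(ev, aoi=aoi))
    return out


# ---------------------------------------------------------------------------
# counterbalance and canonicalization

@dataclass(frozen=True)
class CounterbalanceState:
    player_axis: str = "rows"        # "rows" | "columns"
    own_color: str = "green"         # "green" | "blue" (cosmetic; no remap)
    own_corner: str = "top_left"     # "top_left" | "bottom_right"
    row_swapped: bool = False
    col_swapped: bool = False

    def __post_init__(self) -> None:
        if self.player_axis not in ("rows", "columns"):
            raise ValueError(f"invalid player_axis {self.player_axis!r}")
        if self.own_color not in ("green", "blue"):
            raise ValueError(f"invalid own_color {self.own_color!r}")
        if self.own_corner not in ("top_left", "bottom_right"):
            raise ValueError(f"invalid own_corner {self.own_corner!r}")


IDENTITY_CB = CounterbalanceState()


@dataclass(frozen=True)
class TrialRecord:
    """One play of one game: choice, response time and the ordered fixation
    events.  ``choice`` is a presentation key code (up/down/left/right)
    before canonicalization and 'top'/'bottom' afterwards."""

    participant: str
    trial_index: int
    game_id: str
    choice: str
    rt_ms: float
    fixations: tuple[FixationEvent, ...]
    cb: CounterbalanceState = IDENTITY_CB
    canonical: bool = False
    censored: bool = False


def presentation_label_map(cb: CounterbalanceState) -> dict[int, int]:
    """Map canonical payoff labels (participant = row player, own payoffs
    odd, unswapped) to presentation slots under a counterbalance state."""
    mapping = {}
    for i in range(1, 9):
        lab = PayoffLabel(i)
        own = lab.owner == "self"
        ownact = lab.row          # participant's action: "top"/"bottom"
        othact = lab.col          # other's action: "left"/"right"
        if cb.player_axis == "rows":
            srow = ownact
            scol = othact
            if cb.row_swapped:
                srow = "bottom" if srow == "top" else "top"
            if cb.col_swapped:
                scol = "right" if scol == "left" else "left"
        else:
            # participant plays columns: own actions lie on screen columns
            scol = "left" if ownact == "top" else "right"
            srow = "top" if othact == "left" else "bottom"
            if cb.col_swapped:
                scol = "right" if scol == "left" else "left"
            if cb.row_swapped:
                srow = "bottom" if srow == "top" else "top"
        base = 1 + (4 if srow == "bottom" else 0) + (2 if scol == "right" else 0)
        at_top_left = own == (cb.own_corner == "top_left")
        mapping[i] = base if at_top_left else base + 1
    return mapping


def canonical_label_map(cb: CounterbalanceState) -> dict[int, int]:
    """Inverse of ``presentation_label_map``: presentation slot ->
    canonical payoff label."""
    return {v: k for k, v in presentation_label_map(cb).items()}


_ROW_KEYS = {"up", "down"}
_COL_KEYS = {"left", "right"}


def canonical_choice(choice: str, cb: CounterbalanceState) -> str:
    """Translate a presentation key code into the canonical top/bottom
    choice of the participant's own action."""
    if cb.player_axis == "rows":
        if choice not in _ROW_KEYS:
            raise ValueError(f"row player cannot produce choice code {choice!r}")
        top = (choice == "up") != cb.row_swapped
    else:
        if choice not in _COL_KEYS:
            raise ValueError(f"column player cannot produce choice code {choice!r}")
        top = (choice == "left") != cb.col_swapped
    return "top" if top else "bottom"


def canonicalize(trial: TrialRecord, cb: CounterbalanceState | None = None) -> TrialRecord:
    """Recode a presentation-frame trial into the canonical frame: AOI
    labels become payoff labels (own payoffs odd, participant = row player,
    unswapped), and the choice becomes 'top' or 'bottom'."""
    if trial.canonical:
        raise ValueError("trial is already canonical")
    cb = cb if cb is not None else trial.cb
    label_map = canonical_label_map(cb)
    fixations = tuple(
        replace(f, aoi=label_map[f.aoi] if f.aoi is not None else None)
        for f in trial.fixations
    )
    return replace(
        trial,
        fixations=fixations,
        choice=canonical_choice(trial.choice, cb),
        cb=cb,
        canonical=True,
    )


# ---------------------------------------------------------------------------
# transition taxonomy

@dataclass(frozen=True)
class TransitionClass:
    category: str                    # within_cell | within_column | within_row | rare | repeat
    changes: frozenset[str]          # subset of {owner, own_action, other_action}


def classify_transition(a: int | PayoffLabel, b: int | PayoffLabel) -> TransitionClass:
    """Classify an ordered transition by which payoff attributes change.

    Exactly one change gives a common transition: owner only -> within_cell
    (e.g. y1->y2); own action only -> within_column (e.g. y1->y5); other's
    action only -> within_row (e.g. y1->y3).  Two or more changes -> rare;
    no change -> repeat.
    """
    la = a if isinstance(a, PayoffLabel) else PayoffLabel(a)
    lb = b if isinstance(b, PayoffLabel) else PayoffLabel(b)
    changes = set()
    if la.owner != lb.owner:
        changes.add("owner")
    if la.row != lb.row:
        changes.add("own_action")
    if la.col != lb.col:
        changes.add("other_action")
    if not changes:
        category = "repeat"
    elif len(changes) >= 2:
        category = "rare"
    else:
        category = {
            "owner": "within_cell",
            "own_action": "within_column",
            "other_action": "within_row",
        }[next(iter(changes))]
    return TransitionClass(category=category, changes=frozenset(changes))


# ---------------------------------------------------------------------------
# tallies

@dataclass
class TransitionTally:
    """Ordered 8x8 transition counts (diagonal excluded), per participant
    and optional strata, stored long-form.

    ``table`` columns: participant, <strata...>, from_label, to_label,
    count.  ``repeats`` holds same-AOI re-fixation counts when those are not
    collapsed."""

    table: pd.DataFrame
    strata: tuple[str, ...] = ()
    repeats: int = 0

    def matrix(self, participant: str | None = None, **stratum: str) -> np.ndarray:
        df = self.table
        if participant is not None:
            df = df[df["participant"] == participant]
        for k, v in stratum.items():
            df = df[df[k] == v]
        m = np.zeros((8, 8), dtype=int)
        grouped = df.groupby(["from_label", "to_label"])["count"].sum()
        for (a, b), c in grouped.items():
            m[a - 1, b - 1] = c
        return m

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    def participants(self) -> list[str]:
        return sorted(self.table["participant"].unique())


_VALID_STRATA = {"half", "choice", "game"}


def _gaze_segments(
    fixations: Sequence[FixationEvent], collapse_repeats: bool
) -> tuple[list[int], int]:
    """Labelled gaze sequence(s): unlabelled fixations break the sequence;
    consecutive same-AOI fixations optionally collapse into one gaze.
    Returns the concatenated gaze list with None sentinels at breaks, and
    the number of repeats collapsed or observed."""
    gazes: list[int | None] = []
    repeats = 0
    prev: int | None = None
    for f in fixations:
        if f.aoi is None:
            if gazes and gazes[-1] is not None:
                gazes.append(None)
            prev = None
            continue
        if prev is not None and f.aoi == prev:
            repeats += 1
            if collapse_repeats:
                continue
        gazes.append(f.aoi)
        prev = f.aoi
    return gazes, repeats


def transition_tally(
    trials: Iterable[TrialRecord],
    strata: Sequence[str] = (),
    collapse_repeats: bool = True,
) -> TransitionTally:
    """Count ordered transitions between consecutive distinct-AOI gazes.

    Unlabelled fixations break sequences.  Consecutive fixations within the
    same AOI are collapsed into a single gaze by default (repeats are
    counted separately and never enter the 8x8 matrix).  Optional strata:
    'half' (transition in the first or second half of the trial's gaze
    sequence, middle assigned to the second half), 'choice' (the trial's
    canonical choice) and 'game'.
    """
    strata = tuple(strata)
    bad = set(strata) - _VALID_STRATA
    if bad:
        raise ValueError(f"unknown strata {sorted(bad)}")
    rows: dict[tuple, int] = {}
    repeats_total = 0
    for trial in trials:
        if not trial.canonical:
            raise ValueError("transition_tally requires canonical trials")
        gazes, repeats = _gaze_segments(trial.fixations, collapse_repeats)
        repeats_total += repeats
        # transitions within contiguous labelled runs
        pairs = []
        for a, b in zip(gazes, gazes[1:]):
            if a is not None and b is not None and a != b:
                pairs.append((a, b))
        m = len(pairs)
        for t, (a, b) in enumerate(pairs):
            key = [trial.participant]
            for s in strata:
                if s == "half":
                    key.append("first" if t < m / 2 - 0.5 else "second")
                elif s == "choice":
                    key.append(trial.choice)
                else:
                    key.append(trial.game_id)
            key.extend([a, b])
            k = tuple(key)
            rows[k] = rows.get(k, 0) + 1
    cols = ["participant", *strata, "from_label", "to_label"]
    table = pd.DataFrame(
        [(*k, v) for k, v in rows.items()], columns=[*cols, "count"]
    )
    if table.empty:
        table = pd.DataFrame(columns=[*cols, "count"])
    return TransitionTally(table=table, strata=strata, repeats=repeats_total)


# ---------------------------------------------------------------------------
# gaze-bias curves and summaries

_TOP_LABELS = {1, 2, 3, 4}
_OWN_LABELS = {1, 3, 5, 7}
_LEFT_LABELS = {1, 2, 5, 6}


def gaze_bias_curve(
    trials: Iterable[TrialRecord], n_bins: int = 10
) -> pd.DataFrame:
    """Decile gaze curves conditioned on choice.

    Each trial's labelled fixations are placed into ``n_bins`` time bins by
    fractional position ((index - 0.5) / n, so short trials populate all
    bins), and within each bin the proportion of fixations to top-row, own,
    and left-column payoffs is computed separately for top- and
    bottom-choosing trials.  Trials with no labelled fixations are excluded
    (logged).

    Returns a long DataFrame: bin, choice, measure (top/own/left),
    proportion, n.
    """
    counts = {}  # (bin, choice, measure) -> [hits, n]
    excluded = 0
    for trial in trials:
        if not trial.canonical:
            raise ValueError("gaze_bias_curve requires canonical trials")
        labels = [f.aoi for f in trial.fixations if f.aoi is not None]
        if not labels:
            excluded += 1
            continue
        m = len(labels)
        for i, lab in enumerate(labels):
            b = min(int((i + 0.5) / m * n_bins), n_bins - 1)
            for measure, members in (
                ("top", _TOP_LABELS), ("own", _OWN_LABELS), ("left", _LEFT_LABELS)
            ):
                key = (b, trial.choice, measure)
                hits, n = counts.get(key, (0, 0))
                counts[key] = (hits + (lab in members), n + 1)
    if excluded:
        logger.info("gaze_bias_curve: excluded %d trials with no labelled fixations",
                    excluded)
    rows = [
        {"bin": b, "choice": c, "measure": m, "proportion": h / n, "n": n}
        for (b, c, m), (h, n) in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def summary_stats(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Per-participant process summaries: mean fixations per game, mean
    fixation duration, own-payoff fixation proportion, and the common share
    of transitions (common / (common + rare), repeats excluded).  The final
    row pools all participants."""
    per: dict[str, dict[str, list]] = {}
    trials = list(trials)
    for trial in trials:
        if not trial.canonical:
            raise ValueError("summary_stats requires canonical trials")
        d = per.setdefault(trial.participant, {
            "n_fix": [], "durations": [], "own": [], "common": 0, "rare": 0,
        })
        d["n_fix"].append(len(trial.fixations))
        d["durations"].extend(f.duration_ms for f in trial.fixations)
        d["own"].extend(
            f.aoi in _OWN_LABELS for f in trial.fixations if f.aoi is not None
        )
        gazes, _ = _gaze_segments(trial.fixations, collapse_repeats=True)
        for a, b in zip(gazes, gazes[1:]):
            if a is None or b is None or a == b:
                continue
            cat = classify_transition(a, b).category
            if cat == "rare":
                d["rare"] += 1
            else:
                d["common"] += 1
    rows = []

    def _row(name: str, d: dict) -> dict:
        ct = d["common"] + d["rare"]
        return {
            "participant": name,
            "n_trials": len(d["n_fix"]),
            "fixations_per_game": float(np.mean(d["n_fix"])) if d["n_fix"] else np.nan,
            "mean_fixation_duration_ms": float(np.mean(d["durations"])) if d["durations"] else np.nan,
            "own_fixation_proportion": float(np.mean(d["own"])) if d["own"] else np.nan,
            "common_transition_share": d["common"] / ct if ct else np.nan,
        }

    for p in sorted(per):
        rows.append(_row(p, per[p]))
    pooled = {
        "n_fix": sum((d["n_fix"] for d in per.values()), []),
        "durations": sum((d["durations"] for d in per.values()), []),
        "own": sum((d["own"] for d in per.values()), []),
        "common": sum(d["common"] for d in per.values()),
        "rare": sum(d["rare"] for d in per.values()),
    }
    rows.append(_row("pooled", pooled))
    return pd.DataFrame(rows)
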