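"""Saturated log-linear modelling of the 24 common transition frequencies.

The 24 common ordered transitions form a balanced 3 x 8 cross: three
transition types (within-cell, within-column, within-row; 8 transitions
each) by eight destination payoffs.  The baseline design codes the
destination with +-1 dummies (own, top, left and their interactions) and the
type with two orthogonal contrasts, giving a square, full-rank, orthogonal
24 x 24 matrix: the model is saturated and the per-participant solve on log
counts is exact, so fitted counts reproduce observed counts.

Because every column is orthogonal to the intercept, exp(intercept) is
exactly the geometric mean of the 24 counts, and because ``own`` is +-1
coded, the implied proportion of fixations to own payoffs is
``c / (c + 1/c)`` for an exponentiated own coefficient ``c`` (1.20 gives
0.59).

Two extended designs cross the baseline columns with covariates: the *game*
scheme with the scaled strategic differences (and their product), and the
*gaze-bias* scheme with trial-half and choice indicators.

Point estimates aggregate per-participant coefficients as geometric means
across participants; intervals come from a participant-level bootstrap.
This two-stage estimator replaces a mixed-effects Poisson regression; for
the saturated baseline the point estimates are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .games import Game, PayoffLabel
from .gaze import TransitionTally, classify_transition

__all__ = [
    "COMMON_TRANSITIONS",
    "TransitionDesign",
    "TransitionModelFit",
    "build_design",
    "fit_loglinear",
    "own_proportion_from_coef",
]


def _common_transitions() -> list[tuple[int, int]]:
    out = []
    for a, b in itertools.permutations(range(1, 9), 2):
        if classify_transition(a, b).category not in ("rare", "repeat"):
            out.append((a, b))
    return out


#: The 24 common ordered transitions (deterministic order).
COMMON_TRANSITIONS: tuple[tuple[int, int], ...] = tuple(_common_transitions())

_DEST_TERMS = ("own", "top", "left", "own:top", "own:left", "top:left",
               "own:top:left")


def _dest_row(b: int) -> dict[str, float]:
    lab = PayoffLabel(b)
    own = 1.0 if lab.owner == "self" else -1.0
    top = 1.0 if lab.row == "top" else -1.0
    left = 1.0 if lab.col == "left" else -1.0
    return {
        "intercept": 1.0,
        "own": own, "top": top, "left": left,
        "own:top": own * top, "own:left": own * left, "top:left": top * left,
        "own:top:left": own * top * left,
    }


def _type_contrasts(a: int, b: int) -> tuple[float, float]:
    """Orthogonal contrasts for the transition type: ``cell`` separates
    within-cell from between-cell transitions (2, -1, -1) and ``axis``
    separates within-column from within-row (0, +1, -1)."""
    cat = classify_transition(a, b).category
    if cat == "within_cell":
        return 2.0, 0.0
    if cat == "within_column":
        return -1.0, 1.0
    if cat == "within_row":
        return -1.0, -1.0
    raise ValueError(f"transition {a}->{b} is not common")


def _baseline_matrix() -> pd.DataFrame:
    rows = []
    index = []
    for a, b in COMMON_TRANSITIONS:
        base = _dest_row(b)
        cell, axis = _type_contrasts(a, b)
        row = dict(base)
        row["cell"] = cell
        row["axis"] = axis
        for t in _DEST_TERMS:
            row[f"cell:{t}"] = cell * base[t]
            row[f"axis:{t}"] = axis * base[t]
        rows.append(row)
        index.append(f"{a}->{b}")
    cols = (["intercept", *_DEST_TERMS, "cell"]
            + [f"cell:{t}" for t in _DEST_TERMS]
            + ["axis"] + [f"axis:{t}" for t in _DEST_TERMS])
    return pd.DataFrame(rows, index=index)[cols]


@dataclass(frozen=True)
class TransitionDesign:
    """Design matrix for the log-linear transition model.

    ``row_meta`` aligns each row of ``X`` with the observable cell it
    models (from_label, to_label plus any stratifying covariates)."""

    scheme: str
    X: pd.DataFrame
    row_meta: pd.DataFrame
    game_pairs: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X.to_numpy()))


def build_design(scheme: str, games: list[Game] | None = None) -> TransitionDesign:
    """Build the design for one of the three schemes.

    ``baseline``: the square 24x24 saturated design.  ``game``: baseline
    columns crossed with the scaled differences zL = d_left/6,
    zR = d_right/6 and their product 2*zL*zR (each scaled so a coefficient
    is the effect of the difference moving from its minimum to its maximum);
    rows are the 24 transitions within each distinct (d_left, d_right)
    pair.  ``gaze_bias``: baseline crossed with half (+1 second half),
    choice (+1 top) and their product; rows are the 24 transitions within
    each half x choice stratum.
    """
    base = _baseline_matrix()
    meta_base = pd.DataFrame(
        [{"from_label": a, "to_label": b} for a, b in COMMON_TRANSITIONS]
    )
    if scheme == "baseline":
        return TransitionDesign(scheme=scheme, X=base.reset_index(drop=True),
                                row_meta=meta_base)
    if scheme == "game":
        if games is None:
            raise ValueError("game scheme requires the games list")
        pairs = sorted({(g.d_left, g.d_right) for g in games})
        game_pairs = {g.game_id: (g.d_left, g.d_right) for g in games}
        blocks, metas = [], []
        for dl, dr in pairs:
            zl, zr = dl / 6.0, dr / 6.0
            zlr = 2.0 * zl * zr
            block = pd.concat(
                [base, base.mul(zl).add_prefix("dL:"),
                 base.mul(zr).add_prefix("dR:"),
                 base.mul(zlr).add_prefix("dLdR:")], axis=1,
            )
            blocks.append(block)
            m = meta_base.copy()
            m["d_left"], m["d_right"] = dl, dr
            metas.append(m)
        X = pd.concat(blocks, ignore_index=True)
        meta = pd.concat(metas, ignore_index=True)
        return TransitionDesign(scheme=scheme, X=X, row_meta=meta,
                                game_pairs=game_pairs)
    if scheme == "gaze_bias":
        blocks, metas = [], []
        for half, choice in itertools.product(("first", "second"), ("top", "bottom")):
            h = 1.0 if half == "second" else -1.0
            c = 1.0 if choice == "top" else -1.0
            block = pd.concat(
                [base, base.mul(h).add_prefix("half:"),
                 base.mul(c).add_prefix("choice:"),
                 base.mul(h * c).add_prefix("half:choice:")], axis=1,
            )
            blocks.append(block)
            m = meta_base.copy()
            m["half"], m["choice"] = half, choice
            metas.append(m)
        X = pd.concat(blocks, ignore_index=True)
        meta = pd.concat(metas, ignore_index=True)
        return TransitionDesign(scheme=scheme, X=X, row_meta=meta)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class TransitionModelFit:
    """Fitted log-linear transition model.

    ``exp_coefficients`` are geometric means across participants of the
    per-participant exponentiated coefficients.  ``per_participant`` holds
    the log-scale coefficients (participants x terms).  Participants with a
    zero count received a +0.5 continuity correction before logs and are
    flagged in ``zero_corrected``."""

    scheme: str
    exp_coefficients: pd.Series
    per_participant: pd.DataFrame
    zero_corrected: list[str]
    design: TransitionDesign
    counts: pd.DataFrame  # participants x design rows, post-correction

    def fitted_counts(self, participant: str) -> np.ndarray:
        beta = self.per_participant.loc[participant].to_numpy()
        return np.exp(self.design.X.to_numpy() @ beta)

    def bootstrap_ci(
        self, rng: np.random.Generator, n_boot: int = 500,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Participant-level bootstrap percentile intervals for the
        exponentiated, geometric-mean-aggregated coefficients."""
        P = self.per_participant.to_numpy()
        n = P.shape[0]
        stats = np.empty((n_boot, P.shape[1]))
        for i in range(n_boot):
            idx = rng.integers(n, size=n)
            stats[i] = np.exp(P[idx].mean(axis=0))
        lo = np.quantile(stats, alpha / 2, axis=0)
        hi = np.quantile(stats, 1 - alpha / 2, axis=0)
        return pd.DataFrame(
            {"exp_coefficient": self.exp_coefficients,
             "ci_low": lo, "ci_high": hi},
            index=self.per_participant.columns,
        )

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table in the section layout of the published
        coefficient table (section, term, exp_coefficient, scheme)."""
        rows = []
        for term, value in self.exp_coefficients.items():
            stem = term.split(":", 1)[-1] if term.split(":")[0] in (
                "dL", "dR", "dLdR", "half", "choice") else term
            if stem.startswith("cell"):
                section = "within_vs_between_cell"
            elif stem.startswith("axis"):
                section = "row_vs_column"
            else:
                section = "fixation_frequencies"
            rows.append({"section": section, "term": term,
                         "exp_coefficient": value, "scheme": self.scheme})
        return pd.DataFrame(rows)


def _counts_for_design(
    tally: TransitionTally, design: TransitionDesign, participant: str
) -> np.ndarray:
    df = tally.table[tally.table["participant"] == participant]
    counts = np.zeros(len(design.row_meta))
    if design.scheme == "baseline":
        agg = df.groupby(["from_label", "to_label"])["count"].sum()
        for i, r in design.row_meta.iterrows():
            counts[i] = agg.get((r["from_label"], r["to_label"]), 0)
    elif design.scheme == "game":
        if "game" not in tally.strata:
            raise ValueError("game scheme requires a game-stratified tally")
        df = df.copy()
        df["pair"] = df["game"].map(design.game_pairs)
        agg = df.groupby(["pair", "from_label", "to_label"])["count"].sum()
        for i, r in design.row_meta.iterrows():
            key = ((r["d_left"], r["d_right"]), r["from_label"], r["to_label"])
            counts[i] = agg.get(key, 0)
    else:  # gaze_bias
        if not {"half", "choice"} <= set(tally.strata):
            raise ValueError("gaze_bias scheme requires half and choice strata")
        agg = df.groupby(["half", "choice", "from_label", "to_label"])["count"].sum()
        for i, r in design.row_meta.iterrows():
            key = (r["half"], r["choice"], r["from_label"], r["to_label"])
            counts[i] = agg.get(key, 0)
    return counts


def fit_loglinear(
    tally: TransitionTally, design: TransitionDesign
) -> TransitionModelFit:
    """Fit the log-linear model per participant and aggregate.

    Each participant's counts are solved on the log scale — exactly for the
    square saturated baseline (fitted counts equal observed counts), by
    least squares for the extended schemes.  Zero counts receive a +0.5
    continuity correction (flagged).  Coefficients are aggregated across
    participants as geometric means (arithmetic means of logs).
    """
    X = design.X.to_numpy()
    participants = tally.participants()
    if not participants:
        raise ValueError("empty tally")
    betas, corrected, count_rows = [], [], []
    square = X.shape[0] == X.shape[1]
    for p in participants:
        c = _counts_for_design(tally, design, p)
        if np.any(c == 0):
            corrected.append(p)
            c = c + 0.5
        logc = np.log(c)
        if square:
            beta = np.linalg.solve(X, logc)
        else:
            beta, *_ = np.linalg.lstsq(X, logc, rcond=None)
        betas.append(beta)
        count_rows.append(c)
    per = pd.DataFrame(betas, index=participants, columns=design.X.columns)
    exp_coef = pd.Series(
        np.exp(per.to_numpy().mean(axis=0)), index=design.X.columns,
        name="exp_coefficient",
    )
    counts = pd.DataFrame(count_rows, index=participants)
    return TransitionModelFit(
        scheme=design.scheme,
        exp_coefficients=exp_coef,
        per_participant=per,
        zero_corrected=corrected,
        design=design,
        counts=counts,
    )


def own_proportion_from_coef(c: float) -> float:
    """Proportion of fixations to the player's own payoffs implied by an
    exponentiated +-1-coded own coefficient: ``c / (c + 1/c)``.  At the
    published value 1.20 this is 0.59."""
    if c <= 0:
        raise ValueError("coefficient must be positive")
    return c / (c + 1.0 / c)
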