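"""Readers, writers and the end-to-end pipeline.

File schemas (all UTF-8 with headers):

* fixation log (TSV): participant_id, trial_index, game_id, fix_index,
  onset_ms, x_px, y_px, duration_ms — 0-based fixation indices within a
  trial, screen pixels with origin top-left;
* choice log (TSV): participant_id, trial_index, game_id, choice, rt_ms,
  player_axis, own_color, own_corner, row_swapped, col_swapped — ``choice``
  is a presentation key code (up/down for row players, left/right for column
  players);
* games table (CSV): game_id, base_config, d_left, d_right, y1..y8.

``run_pipeline`` chains the stages — synthesis or ingestion, AOI assignment,
canonicalization, tallies, the transition model, gaze-bias curves, the
choice-model battery, and the level-k mixture fit — writes every stage
output plus a manifest with checksums, and returns the report dictionary.
All randomness flows from a single configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import choicemodels, gaze, levelk, transition_model
from .games import default_game_grid, games_from_frame
from .gaze import CounterbalanceState, FixationEvent, TrialRecord
from .synth import (
    CHOICE_COLUMNS,
    FIXATION_COLUMNS,
    CohortConfig,
    generate_cohort,
)

__all__ = [
    "read_fixation_log",
    "read_choice_log",
    "read_games_csv",
    "write_cohort",
    "trials_from_logs",
    "run_pipeline",
]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_fixation_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a fixation log TSV.

    Enforces ordering by (participant, trial, fix_index); a non-monotone
    fix_index or non-positive duration raises with the offending row
    number (1-based, excluding the header)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, FIXATION_COLUMNS, f"fixation log {path}")
    if len(df) == 0:
        return df
    bad = df.index[df["duration_ms"] <= 0]
    if len(bad):
        raise SchemaError(f"fixation log {path}: non-positive duration at row {bad[0] + 1}")
    for (pid, tid), grp in df.groupby(["participant_id", "trial_index"], sort=False):
        fi = grp["fix_index"].to_numpy()
        if np.any(np.diff(fi) <= 0):
            row = grp.index[int(np.argmax(np.diff(fi) <= 0)) + 1] + 1
            raise SchemaError(
                f"fixation log {path}: fix_index not strictly increasing for "
                f"participant {pid} trial {tid} at row {row}"
            )
    return df.sort_values(
        ["participant_id", "trial_index", "fix_index"]
    ).reset_index(drop=True)


def read_choice_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CHOICE_COLUMNS, f"choice log {path}")
    return df


def read_games_csv(path: str | Path):
    return games_from_frame(pd.read_csv(path))


def write_cohort(data, out_dir: str | Path) -> dict[str, str]:
    """Write a cohort's fixation TSV, choice TSV, games CSV and manifest
    JSON; returns path -> sha256 checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixations.tsv": lambda p: data.fixations.to_csv(p, sep="\t", index=False),
        "choices.tsv": lambda p: data.choices.to_csv(p, sep="\t", index=False),
        "games.csv": lambda p: data.games.to_csv(p, index=False),
        "manifest.json": lambda p: p.write_text(
            json.dumps(data.manifest, indent=2, default=str)
        ),
    }
    checksums = {}
    for name, writer in paths.items():
        p = out / name
        writer(p)
        checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return checksums


def trials_from_logs(
    fixations: pd.DataFrame, choices: pd.DataFrame
) -> list[TrialRecord]:
    """Join fixation and choice logs into presentation-frame trial records
    (AOIs unassigned; call gaze.assign_fixations + gaze.canonicalize next)."""
    fix_groups = {
        key: grp for key, grp in fixations.groupby(["participant_id", "trial_index"])
    }
    trials = []
    for _, row in choices.iterrows():
        key = (row["participant_id"], row["trial_index"])
        grp = fix_groups.get(key)
        events = tuple(
            FixationEvent(
                onset_ms=float(f.onset_ms), duration_ms=float(f.duration_ms),
                x_px=float(f.x_px), y_px=float(f.y_px),
            )
            for f in (grp.itertuples() if grp is not None else ())
        )
        cb = CounterbalanceState(
            player_axis=row["player_axis"], own_color=row["own_color"],
            own_corner=row["own_corner"],
            row_swapped=bool(row["row_swapped"]),
            col_swapped=bool(row["col_swapped"]),
        )
        trials.append(TrialRecord(
            participant=row["participant_id"],
            trial_index=int(row["trial_index"]),
            game_id=row["game_id"],
            choice=row["choice"],
            rt_ms=float(row["rt_ms"]),
            fixations=events,
            cb=cb,
        ))
    return trials


DEFAULT_MODELS = (
    "intercept", "attributes", "attributes_simple", "fixations",
    "attributes_fixations", "last_fixation", "transitions",
    "transitions_attributes", "improper_fixations", "improper_transitions",
)


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text)
    return dict(config)


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full analysis chain and write all stage outputs.

    ``config`` (dict, or YAML/JSON path) keys: ``seed`` (int), ``out_dir``
    (path), and either a ``synth`` block (CohortConfig keyword overrides)
    or an ``inputs`` block with ``fixations``/``choices``/``games`` paths;
    optional ``models`` (names for the choice battery) and ``layout`` is
    the default screen layout.  Returns the report dictionary, also written
    as report.json.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "pipeline_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = gaze.default_layout()

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        return wrap

    # --- inputs
    if "synth" in cfg:
        synth_cfg = CohortConfig(**{"seed": seed, **cfg["synth"]})
        data = _stage("synth")(generate_cohort, synth_cfg)
        checksums = write_cohort(data, out_dir)
        fix_df, choice_df = data.fixations, data.choices
        games = games_from_frame(data.games)
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        fix_df = _stage("ingest")(read_fixation_log, inp["fixations"])
        choice_df = _stage("ingest")(read_choice_log, inp["choices"])
        games = (read_games_csv(inp["games"]) if "games" in inp
                 else default_game_grid())
        checksums = {}
    else:
        raise ValueError("config must contain a 'synth' or 'inputs' block")

    # --- canonical process data
    trials = _stage("ingest")(trials_from_logs, fix_df, choice_df)
    canonical = []
    for t in trials:
        labelled = gaze.assign_fixations(t.fixations, layout)
        canonical.append(gaze.canonicalize(replace(t, fixations=tuple(labelled))))

    # --- process statistics
    summary = _stage("summary")(gaze.summary_stats, canonical)
    tally = _stage("tally")(gaze.transition_tally, canonical)
    design = transition_model.build_design("baseline")
    tfit = _stage("transition_model")(transition_model.fit_loglinear, tally, design)
    own_coef = float(tfit.exp_coefficients["own"])
    curves = _stage("gaze_bias")(gaze.gaze_bias_curve, canonical)

    # --- choice models
    model_names = tuple(cfg.get("models", DEFAULT_MODELS))
    comparison = _stage("choicemodels")(
        choicemodels.compare_models, canonical, games, model_names
    )

    # --- level-k mixture
    gmap = {g.game_id: g for g in games}
    per_game = {}
    for t in canonical:
        tc, n = per_game.get(t.game_id, (0, 0))
        per_game[t.game_id] = (tc + (t.choice == "top"), n + 1)
    gids = sorted(per_game)
    mixture = _stage("levelk")(
        levelk.fit_mixture,
        np.array([per_game[g][0] for g in gids], dtype=float),
        np.array([per_game[g][1] for g in gids], dtype=float),
        [gmap[g] for g in gids],
    )

    # --- write outputs
    outputs = {
        "summary_stats.csv": summary,
        "transition_tally.csv": tally.table,
        "transition_coefficients.csv": tfit.to_frame(),
        "gaze_bias_curves.csv": curves,
        "model_comparison.csv": comparison,
    }
    for name, df in outputs.items():
        p = out_dir / name
        df.to_csv(p, index=False)
        checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()

    pooled = summary[summary["participant"] == "pooled"].iloc[0]
    report = {
        "seed": seed,
        "n_participants": int(len(summary) - 1),
        "n_trials": len(canonical),
        "summary": {
            "fixations_per_game": float(pooled["fixations_per_game"]),
            "mean_fixation_duration_ms": float(pooled["mean_fixation_duration_ms"]),
            "own_fixation_proportion": float(pooled["own_fixation_proportion"]),
            "common_transition_share": float(pooled["common_transition_share"]),
        },
        "transition_model": {
            "own_exp_coefficient": own_coef,
            "own_proportion_implied": transition_model.own_proportion_from_coef(own_coef),
            "intercept_exp_coefficient": float(tfit.exp_coefficients["intercept"]),
            "zero_corrected_participants": len(tfit.zero_corrected),
        },
        "mixture_fit": {
            "p0": mixture.weights.p0, "p1": mixture.weights.p1,
            "p2": mixture.weights.p2, "loglik": mixture.loglik,
            "converged": mixture.converged,
            "identifiability_warning": mixture.identifiability_warning,
        },
        "model_comparison": comparison.to_dict(orient="records"),
        "checksums": checksums,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
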