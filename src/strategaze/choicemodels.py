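"""Logistic models fitting choices from payoffs, fixations and transitions.

The suite mirrors the standard model-comparison battery for process data in
2x2 games: an intercept baseline, an *attributes* model (free dummies for
each strategic-difference level, base configuration and their interactions —
effectively one coefficient per game), *fixations* (per-AOI fixation counts
F1..F8), *transitions* (per-ordered-pair counts T_ij), *last fixation* (the
row of the final labelled fixation), combined models, and "improper"
single-coefficient variants that constrain all gaze effects to a common
magnitude.

Fits are compared on in-sample classification accuracy at 0.5, a BIC whose
sample-size penalty uses the number of participants (choices are nested
within participants; the correction is a policy, selectable via
``bic_nested``), and the Nagelkerke pseudo-R2, whose additivity supports the
shared/unique variance partition of ``variance_partition``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

from .games import Game
from .gaze import TrialRecord, _gaze_segments

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "ChoiceDesign",
    "ModelFit",
    "build_choice_design",
    "fit_choice_model",
    "bic_nested",
    "cross_validated_accuracy",
    "nagelkerke_r2",
    "variance_partition",
    "last_fixation_correction",
    "compare_models",
]

MODEL_NAMES = (
    "intercept",
    "attributes",
    "attributes_simple",
    "fixations",
    "attributes_fixations",
    "last_fixation",
    "transitions",
    "transitions_attributes",
    "improper_fixations",
    "improper_transitions",
)

_GAZE_BASED = {
    "fixations", "attributes_fixations", "last_fixation", "transitions",
    "transitions_attributes", "improper_fixations", "improper_transitions",
}

_ORDERED_PAIRS = [(a, b) for a, b in itertools.permutations(range(1, 9), 2)]


@dataclass
class ChoiceDesign:
    name: str
    X: pd.DataFrame            # includes the constant column
    y: np.ndarray              # 1 = top
    clusters: np.ndarray       # participant per observation
    n_excluded: int = 0


def _trial_features(trial: TrialRecord) -> dict[str, float]:
    labels = [f.aoi for f in trial.fixations if f.aoi is not None]
    feats: dict[str, float] = {f"F{i}": 0.0 for i in range(1, 9)}
    for lab in labels:
        feats[f"F{lab}"] += 1
    gazes, _ = _gaze_segments(trial.fixations, collapse_repeats=True)
    trans = {f"T{a}{b}": 0.0 for a, b in _ORDERED_PAIRS}
    for a, b in zip(gazes, gazes[1:]):
        if a is not None and b is not None and a != b:
            trans[f"T{a}{b}"] += 1
    feats.update(trans)
    feats["last_fix_top"] = (
        (1.0 if labels[-1] <= 4 else -1.0) if labels else np.nan
    )
    feats["improper_fixations"] = (
        sum(feats[f"F{i}"] for i in (1, 2, 3, 4))
        - sum(feats[f"F{i}"] for i in (5, 6, 7, 8))
    )
    to_top = sum(trans[f"T{a}{b}"] for a in (5, 6, 7, 8) for b in (1, 2, 3, 4))
    to_bot = sum(trans[f"T{a}{b}"] for a in (1, 2, 3, 4) for b in (5, 6, 7, 8))
    feats["improper_transitions"] = to_top - to_bot
    feats["n_labelled"] = len(labels)
    return feats


def build_choice_design(
    trials: list[TrialRecord], spec: str, games: list[Game]
) -> ChoiceDesign:
    """Assemble the predictor table for one named model.

    Gaze-based designs exclude (and log) trials with no labelled fixation.
    The returned design includes its constant column.
    """
    if spec not in MODEL_NAMES:
        raise ValueError(f"unknown model {spec!r}; expected one of {MODEL_NAMES}")
    gmap = {g.game_id: g for g in games}
    rows, y, clusters = [], [], []
    excluded = 0
    for t in trials:
        if not t.canonical:
            raise ValueError("build_choice_design requires canonical trials")
        feats = _trial_features(t)
        if spec in _GAZE_BASED and feats["n_labelled"] == 0:
            excluded += 1
            continue
        g = gmap[t.game_id]
        feats["d_left"], feats["d_right"] = g.d_left, g.d_right
        feats["base_config"] = g.base_config
        rows.append(feats)
        y.append(1.0 if t.choice == "top" else 0.0)
        clusters.append(t.participant)
    if excluded:
        logger.info("%s design: excluded %d trials with no labelled fixations",
                    spec, excluded)
    df = pd.DataFrame(rows)
    const = pd.DataFrame({"const": np.ones(len(df))})

    if spec == "intercept":
        X = const
    elif spec == "attributes":
        X = dmatrix(
            "C(d_left) * C(d_right) * C(base_config)", df,
            return_type="dataframe",
        ).rename(columns={"Intercept": "const"})
    elif spec == "attributes_simple":
        X = pd.concat([const, df[["d_left", "d_right"]]], axis=1)
    elif spec == "fixations":
        X = pd.concat([const, df[[f"F{i}" for i in range(1, 9)]]], axis=1)
    elif spec == "attributes_fixations":
        attrs = build_choice_design(trials, "attributes", games).X
        fix = df[[f"F{i}" for i in range(1, 9)]].reset_index(drop=True)
        X = pd.concat([attrs.reset_index(drop=True), fix], axis=1)
    elif spec == "last_fixation":
        X = pd.concat([const, df[["last_fix_top"]]], axis=1)
    elif spec == "transitions":
        X = pd.concat(
            [const, df[[f"T{a}{b}" for a, b in _ORDERED_PAIRS]]], axis=1
        )
    elif spec == "transitions_attributes":
        attrs = build_choice_design(trials, "attributes", games).X
        tr = df[[f"T{a}{b}" for a, b in _ORDERED_PAIRS]].reset_index(drop=True)
        X = pd.concat([attrs.reset_index(drop=True), tr], axis=1)
    elif spec == "improper_fixations":
        X = pd.concat([const, df[["improper_fixations"]]], axis=1)
    else:  # improper_transitions
        X = pd.concat([const, df[["improper_transitions"]]], axis=1)
    return ChoiceDesign(
        name=spec, X=X.reset_index(drop=True),
        y=np.asarray(y), clusters=np.asarray(clusters),
        n_excluded=excluded,
    )


@dataclass
class ModelFit:
    name: str
    coefficients: pd.Series
    loglik: float
    accuracy: float
    bic_nested: float
    nagelkerke_r2: float
    n_obs: int
    n_clusters: int
    n_params: int
    ridged: bool = False


def _null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def fit_choice_model(design: ChoiceDesign, ridge_alpha: float = 1.0) -> ModelFit:
    """Maximum-likelihood logistic fit of choice on a design.

    Under complete separation or failed convergence the fit falls back to an
    L2-regularized estimate (flagged via ``ridged``) rather than crashing.
    """
    y, X = design.y, design.X
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    # drop collinear columns (free attribute dummies can be redundant)
    Xv = X.to_numpy()
    q, r = np.linalg.qr(Xv)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        X = X.loc[:, keep]
        Xv = X.to_numpy()
    model = sm.Logit(y, Xv)
    ridged = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=500, method="lbfgs")
            if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
                params = res.params
                # complete separation: every margin strictly positive means
                # the MLE is not finite — the ridge fallback applies
                margins = (2 * y - 1) * (Xv @ params)
                if np.all(margins > 0):
                    params = None
        except Exception:
            params = None
        if params is None:
            res = model.fit_regularized(
                disp=0, alpha=ridge_alpha, L1_wt=0.0, maxiter=500
            )
            params = np.asarray(res.params)
            ridged = True
    eta = Xv @ params
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = float(y @ np.log(p) + (1 - y) @ np.log1p(-p))
    acc = float(np.mean((p >= 0.5) == (y == 1)))
    n_clusters = len(np.unique(design.clusters))
    k = X.shape[1]
    ll_null = _null_loglik(y)
    r2 = nagelkerke_r2(max(ll, ll_null), ll_null, len(y))
    return ModelFit(
        name=design.name,
        coefficients=pd.Series(params, index=X.columns),
        loglik=ll,
        accuracy=acc,
        bic_nested=bic_nested(ll, k, n_clusters),
        nagelkerke_r2=r2,
        n_obs=len(y),
        n_clusters=n_clusters,
        n_params=k,
        ridged=ridged,
    )


def cross_validated_accuracy(
    design: ChoiceDesign, n_folds: int = 5,
    rng: np.random.Generator | None = None,
    ridge_alpha: float = 1.0,
) -> float:
    """Cluster-wise k-fold out-of-sample accuracy at threshold 0.5.

    Folds split participants, never observations, so the estimate respects
    the nesting of choices within participants.  In-sample accuracy is the
    headline comparison metric; this is the appropriate check when a model
    has enough parameters for in-sample optimism to matter (e.g. verifying
    that gaze models are at chance on data where gaze is independent of
    choice)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    clusters = np.unique(design.clusters)
    if len(clusters) < n_folds:
        raise ValueError("need at least as many clusters as folds")
    perm = rng.permutation(len(clusters))
    folds = np.array_split(clusters[perm], n_folds)
    Xv = design.X.to_numpy()
    y = design.y
    correct = 0
    for fold in folds:
        test = np.isin(design.clusters, fold)
        train = ~test
        model = sm.Logit(y[train], Xv[train])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=500, method="lbfgs")
                params = res.params
                if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
                    raise ValueError
            except Exception:
                params = np.asarray(model.fit_regularized(
                    disp=0, alpha=ridge_alpha, L1_wt=0.0, maxiter=500
                ).params)
        pred = (Xv[test] @ params) >= 0
        correct += int(np.sum(pred == (y[test] == 1)))
    return correct / len(y)


def bic_nested(loglik: float, n_params: int, n_clusters: int) -> float:
    """BIC with the sample-size penalty taken at the number of clusters
    (participants), reflecting the nesting of choices within participants:
    ``-2*loglik + n_params*log(n_clusters)``."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_clusters)


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2: the Cox-Snell ratio rescaled to [0, 1].

    ``(1 - exp(2*(ll_null - ll_model)/n)) / (1 - exp(2*ll_null/n))``; 0 when
    the model adds nothing over the null, 1 for a perfect fit."""
    if ll_model < ll_null - 1e-9:
        raise ValueError("model log-likelihood below null log-likelihood")
    denom = 1.0 - np.exp(2.0 * ll_null / n)
    if denom <= 0:
        return 0.0
    return float((1.0 - np.exp(2.0 * (ll_null - ll_model) / n)) / denom)


def variance_partition(
    r2_a: float, r2_b: float, r2_ab: float, tolerance: float = 1e-6
) -> dict[str, float | bool]:
    """Partition the joint pseudo-R2 of two predictor sets into shared and
    unique components: shared = r2_a + r2_b - r2_ab, unique_a = r2_ab -
    r2_b, unique_b = r2_ab - r2_a.  A negative shared component beyond
    tolerance (suppression) is flagged, not raised."""
    for name, v in (("r2_a", r2_a), ("r2_b", r2_b), ("r2_ab", r2_ab)):
        if not -tolerance <= v <= 1 + tolerance:
            raise ValueError(f"{name} must be in [0, 1]")
    shared = r2_a + r2_b - r2_ab
    return {
        "shared": shared,
        "unique_a": r2_ab - r2_b,
        "unique_b": r2_ab - r2_a,
        "suppression": bool(shared < -tolerance),
    }


def last_fixation_correction(
    design_transitions: ChoiceDesign, last_fix_top: np.ndarray
) -> tuple[ModelFit, ModelFit]:
    """Correct transition coefficients for the last fixation.

    The between-row transition difference and the last-fixation row are
    linked by an accounting identity (the net difference is 0 or -1
    depending on where the sequence ends), so the last-fixation row is
    entered into the regression alongside the transition counts; the
    returned pair is (corrected fit, uncorrected fit) on identical
    observations.
    """
    last = np.asarray(last_fix_top, dtype=float)
    if len(last) != len(design_transitions.y):
        raise ValueError("last_fix_top must align with the transitions design")
    X = design_transitions.X.copy()
    cols = list(X.columns)
    X.insert(cols.index("const") + 1, "last_fix_top", last)
    corrected = ChoiceDesign(
        name=design_transitions.name + "_lastfix_corrected",
        X=X, y=design_transitions.y, clusters=design_transitions.clusters,
        n_excluded=design_transitions.n_excluded,
    )
    return fit_choice_model(corrected), fit_choice_model(design_transitions)


def compare_models(
    trials: list[TrialRecord],
    games: list[Game],
    models: tuple[str, ...] = MODEL_NAMES,
) -> pd.DataFrame:
    """Fit a battery of choice models and tabulate the comparison
    (model, accuracy, bic, nagelkerke_r2, n_params, n_obs)."""
    rows = []
    for name in models:
        design = build_choice_design(trials, name, games)
        fit = fit_choice_model(design)
        rows.append({
            "model": name,
            "accuracy": fit.accuracy,
            "bic": fit.bic_nested,
            "nagelkerke_r2": fit.nagelkerke_r2,
            "n_params": fit.n_params,
            "n_obs": fit.n_obs,
            "ridged": fit.ridged,
        })
    return pd.DataFrame(rows)
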