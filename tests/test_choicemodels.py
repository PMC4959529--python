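import numpy as np
import pytest
from hypothesis import given, strategies as st

from strategaze.choicemodels import (
    bic_nested,
    build_choice_design,
    compare_models,
    cross_validated_accuracy,
    fit_choice_model,
    last_fixation_correction,
    nagelkerke_r2,
    variance_partition,
)
from strategaze.gaze import FixationEvent, TrialRecord


def _trial(labels, choice="top", participant="p1", game_id=None, trial_index=0):
    fixations = tuple(
        FixationEvent(onset_ms=i * 250.0, duration_ms=250.0, x_px=0, y_px=0,
                      aoi=lab)
        for i, lab in enumerate(labels)
    )
    return TrialRecord(
        participant=participant, trial_index=trial_index,
        game_id=game_id or "b1_dL1_dR1", choice=choice,
        rt_ms=250.0 * len(labels), fixations=fixations, canonical=True,
    )


class TestDesigns:
    def test_improper_fixations_arithmetic(self, game_grid):
        trials = [
            _trial([1, 3, 5], choice="top"),
            _trial([5, 7, 6, 8], choice="bottom", trial_index=1),
        ]
        design = build_choice_design(trials, "improper_fixations", game_grid)
        assert list(design.X["improper_fixations"]) == [1.0, -4.0]

    def test_improper_transitions_antisymmetric_under_mirror(self, game_grid):
        labels = [1, 5, 3, 2, 6, 1, 7]
        mirror = {1: 5, 2: 6, 3: 7, 4: 8, 5: 1, 6: 2, 7: 3, 8: 4}
        mirrored = [mirror[x] for x in labels]
        trials = [
            _trial(labels, choice="top"),
            _trial(mirrored, choice="bottom", trial_index=1),
        ]
        design = build_choice_design(trials, "improper_transitions", game_grid)
        v = design.X["improper_transitions"].to_numpy()
        assert v[0] == -v[1] != 0

    def test_attributes_design_spans_the_games(self, game_grid):
        trials = [
            _trial([1, 3], game_id=g.game_id, trial_index=i,
                   choice="top" if i % 2 else "bottom")
            for i, g in enumerate(game_grid)
        ]
        design = build_choice_design(trials, "attributes", game_grid)
        # free dummies for 4 x 4 x 4 cells: one column per game
        assert design.X.shape == (64, 64)

    def test_gaze_designs_exclude_unlabelled_trials(self, game_grid):
        trials = [
            _trial([None, None], choice="top"),
            _trial([1, 5], choice="bottom", trial_index=1),
        ]
        design = build_choice_design(trials, "fixations", game_grid)
        assert design.n_excluded == 1 and len(design.y) == 1
        attr = build_choice_design(trials, "attributes_simple", game_grid)
        assert attr.n_excluded == 0 and len(attr.y) == 2

    def test_unknown_model_rejected(self, game_grid):
        with pytest.raises(ValueError):
            build_choice_design([], "not_a_model", game_grid)


class TestAccountingIdentity:
    @given(st.lists(st.integers(1, 8), min_size=2, max_size=30))
    def test_between_row_difference_is_zero_or_minus_one(self, labels):
        """Starting from the first fixation's row, (transitions ending top)
        minus (transitions ending bottom) determines the last fixation's
        row: the net difference is 0 when gaze returns to the starting row
        and +-1 when it ends on the other row."""
        to_top = to_bot = 0
        seq = [labels[0]]
        for x in labels[1:]:
            if x != seq[-1]:
                seq.append(x)
        for a, b in zip(seq, seq[1:]):
            if a > 4 and b <= 4:
                to_top += 1
            elif a <= 4 and b > 4:
                to_bot += 1
        net = to_top - to_bot
        first_top = seq[0] <= 4
        last_top = seq[-1] <= 4
        if first_top:
            assert net in (0, -1)
            assert last_top == (net == 0)
        else:
            assert net in (0, 1)
            assert last_top == (net == 1)


class TestFitting:
    def test_intercept_accuracy_is_majority_share(self, game_grid, rng):
        trials = [
            _trial([1, 3], choice="top" if rng.random() < 0.7 else "bottom",
                   trial_index=i)
            for i in range(300)
        ]
        design = build_choice_design(trials, "intercept", game_grid)
        fit = fit_choice_model(design)
        majority = max(np.mean(design.y), 1 - np.mean(design.y))
        assert fit.accuracy == pytest.approx(majority)
        assert fit.nagelkerke_r2 == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovery_on_improper_fixations(self, game_grid, rng):
        """Choices generated from a known logistic on the fixation
        difference return a slope within the fitted CI."""
        true_slope = 0.6
        trials = []
        for i in range(1500):
            labels = list(rng.integers(1, 9, size=12))
            diff = sum(l <= 4 for l in labels) - sum(l > 4 for l in labels)
            p = 1 / (1 + np.exp(-true_slope * diff))
            trials.append(_trial(
                labels, choice="top" if rng.random() < p else "bottom",
                trial_index=i,
            ))
        design = build_choice_design(trials, "improper_fixations", game_grid)
        fit = fit_choice_model(design)
        est = fit.coefficients["improper_fixations"]
        se_ok = abs(est - true_slope) < 0.15
        assert se_ok, est

    def test_separation_falls_back_to_ridge(self, game_grid):
        trials = [
            _trial([1, 1, 3], choice="top", trial_index=i) for i in range(10)
        ] + [
            _trial([5, 7, 5], choice="bottom", trial_index=10 + i)
            for i in range(10)
        ]
        design = build_choice_design(trials, "improper_fixations", game_grid)
        fit = fit_choice_model(design)
        assert fit.ridged
        assert np.all(np.isfinite(fit.coefficients))

    def test_single_class_rejected(self, game_grid):
        trials = [_trial([1, 3], choice="top", trial_index=i) for i in range(5)]
        design = build_choice_design(trials, "intercept", game_grid)
        with pytest.raises(ValueError):
            fit_choice_model(design)


class TestMetrics:
    def test_bic_edge_cases(self):
        assert bic_nested(-100.0, 0, 54) == 200.0
        assert bic_nested(-100.0, 5, 54) > bic_nested(-100.0, 3, 54)
        with pytest.raises(ValueError):
            bic_nested(-1.0, 1, 0)

    def test_nagelkerke_trivial_values(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0
        assert nagelkerke_r2(0.0, -69.3, 100) == pytest.approx(1.0, abs=1e-3)
        with pytest.raises(ValueError):
            nagelkerke_r2(-60.0, -50.0, 100)

    def test_nagelkerke_hand_computed(self):
        """10-observation toy set: ll_null = 10*ln(1/2), ll_model chosen
        freely; value checked against the direct formula."""
        ll_null = 10 * np.log(0.5)
        ll_model = -4.0
        expected = (1 - np.exp(2 * (ll_null - ll_model) / 10)) / (
            1 - np.exp(2 * ll_null / 10)
        )
        assert nagelkerke_r2(ll_model, ll_null, 10) == pytest.approx(expected)

    def test_nagelkerke_invariant_to_cluster_duplication(self, game_grid, rng):
        trials = [
            _trial(list(rng.integers(1, 9, size=8)),
                   choice="top" if rng.random() < 0.5 else "bottom",
                   participant=f"p{i % 4}", trial_index=i)
            for i in range(200)
        ]
        d1 = build_choice_design(trials, "fixations", game_grid)
        f1 = fit_choice_model(d1)
        d1.clusters = np.array([c + "_dup" for c in d1.clusters])
        f2 = fit_choice_model(d1)
        assert f1.nagelkerke_r2 == pytest.approx(f2.nagelkerke_r2)

    def test_variance_partition_published_example(self):
        out = variance_partition(0.56, 0.27, 0.66)
        assert out["shared"] == pytest.approx(0.17, abs=1e-12)
        assert not out["suppression"]

    def test_variance_partition_perfectly_unique(self):
        out = variance_partition(0.5, 0.3, 0.8)
        assert out["shared"] == pytest.approx(0.0, abs=1e-12)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_variance_partition_identity(self, a, b, ab):
        out = variance_partition(a, b, ab)
        total = out["shared"] + out["unique_a"] + out["unique_b"]
        assert total == pytest.approx(ab, abs=1e-9)


class TestCrossValidation:
    def test_detects_real_signal_but_not_noise(self, game_grid, rng):
        """Cluster-wise CV accuracy beats chance when gaze drives choice and
        stays at chance when it does not."""
        signal, noise = [], []
        for i in range(400):
            labels = list(rng.integers(1, 9, size=12))
            top_heavy = sum(l <= 4 for l in labels) > 6
            signal.append(_trial(
                labels, choice="top" if top_heavy else "bottom",
                participant=f"p{i % 10}", trial_index=i,
            ))
            noise.append(_trial(
                labels, choice="top" if rng.random() < 0.5 else "bottom",
                participant=f"p{i % 10}", trial_index=i,
            ))
        d_sig = build_choice_design(signal, "improper_fixations", game_grid)
        d_noi = build_choice_design(noise, "improper_fixations", game_grid)
        cv_rng = np.random.default_rng(1)
        assert cross_validated_accuracy(d_sig, rng=cv_rng) > 0.8
        assert cross_validated_accuracy(d_noi, rng=cv_rng) < 0.58

    def test_requires_enough_clusters(self, game_grid, rng):
        trials = [
            _trial([1, 3], choice="top" if i % 2 else "bottom", trial_index=i)
            for i in range(10)
        ]
        design = build_choice_design(trials, "intercept", game_grid)
        with pytest.raises(ValueError):
            cross_validated_accuracy(design, n_folds=5)


class TestLastFixationCorrection:
    def _cohort(self, rng, n=600):
        """Choice driven purely by the last fixation's row."""
        trials = []
        for i in range(n):
            labels = list(rng.integers(1, 9, size=10))
            choice = "top" if labels[-1] <= 4 else "bottom"
            trials.append(_trial(labels, choice=choice, trial_index=i))
        return trials

    def test_transition_coefficients_shrink(self, game_grid, rng):
        trials = self._cohort(rng)
        design = build_choice_design(trials, "transitions", game_grid)
        last = np.array([
            1.0 if [f.aoi for f in t.fixations][-1] <= 4 else -1.0
            for t in trials
        ])
        corrected, uncorrected = last_fixation_correction(design, last)
        tcols = [c for c in uncorrected.coefficients.index if c.startswith("T")]
        shared = [c for c in tcols if c in corrected.coefficients.index]
        norm_unc = np.linalg.norm(uncorrected.coefficients[shared])
        norm_cor = np.linalg.norm(corrected.coefficients[shared])
        assert norm_cor < norm_unc

    def test_same_observations(self, game_grid, rng):
        trials = self._cohort(rng, n=200)
        design = build_choice_design(trials, "transitions", game_grid)
        last = np.ones(len(design.y))
        last[::2] = -1.0
        corrected, uncorrected = last_fixation_correction(design, last)
        assert corrected.n_obs == uncorrected.n_obs

    def test_misaligned_input_rejected(self, game_grid, rng):
        trials = self._cohort(rng, n=50)
        design = build_choice_design(trials, "transitions", game_grid)
        with pytest.raises(ValueError):
            last_fixation_correction(design, np.ones(len(design.y) + 1))


class TestModelOrdering:
    def test_accuracy_ordering_on_accumulator_cohort(self, small_cohort_trials,
                                                     game_grid):
        """On synthetic cohorts the model accuracies reproduce the expected
        qualitative ranking, and improper models never beat their
        unconstrained counterparts in-sample."""
        comparison = compare_models(
            small_cohort_trials, game_grid,
            models=("intercept", "attributes", "fixations",
                    "attributes_fixations", "transitions",
                    "improper_fixations", "improper_transitions"),
        ).set_index("model")
        acc = comparison["accuracy"]
        assert acc["attributes_fixations"] >= acc["attributes"] - 0.01
        assert acc["attributes"] >= acc["fixations"]
        assert acc["fixations"] >= acc["intercept"]
        assert acc["improper_fixations"] <= acc["fixations"] + 1e-9
        assert acc["improper_transitions"] <= acc["transitions"] + 1e-9
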