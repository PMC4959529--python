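import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strategaze.gaze import (
    CounterbalanceState,
    FixationEvent,
    Layout,
    TrialRecord,
    assign_fixations,
    canonical_label_map,
    canonicalize,
    classify_transition,
    default_layout,
    gaze_bias_curve,
    presentation_label_map,
    summary_stats,
    transition_tally,
)


def _fix(x, y, onset=0.0, dur=250.0, aoi=None):
    return FixationEvent(onset_ms=onset, duration_ms=dur, x_px=x, y_px=y, aoi=aoi)


def _trial(labels, choice="top", participant="p1", game="g1", trial_index=0,
           canonical=True):
    fixations = tuple(
        _fix(0, 0, onset=i * 250.0, aoi=lab) for i, lab in enumerate(labels)
    )
    return TrialRecord(
        participant=participant, trial_index=trial_index, game_id=game,
        choice=choice, rt_ms=250.0 * len(labels), fixations=fixations,
        canonical=canonical,
    )


class TestAssignment:
    def test_center_hit_and_boundary(self):
        layout = default_layout()
        cx, cy = layout.aoi_centers[3]
        events = [
            _fix(cx, cy),             # dead center
            _fix(cx + 99.0, cy),      # inside the 100-px radius
            _fix(cx + 100.0, cy),     # boundary: inclusive
            _fix(cx + 101.0, cy),     # outside
        ]
        out = assign_fixations(events, layout)
        assert [e.aoi for e in out] == [3, 3, 3, None]

    def test_order_preserved(self):
        layout = default_layout()
        pts = [layout.aoi_centers[i] for i in (5, 2, 8)]
        out = assign_fixations([_fix(*p) for p in pts], layout)
        assert [e.aoi for e in out] == [5, 2, 8]

    def test_overlapping_layout_rejected_before_assignment(self):
        centers = dict(default_layout().aoi_centers)
        centers[2] = (centers[1][0] + 150.0, centers[1][1])  # 150 < 2*100
        layout = Layout(aoi_centers=centers)
        with pytest.raises(ValueError, match="overlap"):
            assign_fixations([_fix(0, 0)], layout)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            _fix(0, 0, dur=-1.0)


ALL_STATES = [
    CounterbalanceState(axis, color, corner, bool(rs), bool(cs))
    for axis, color, corner, rs, cs in itertools.product(
        ("rows", "columns"), ("green", "blue"),
        ("top_left", "bottom_right"), (0, 1), (0, 1),
    )
]


class TestCanonicalize:
    def test_identity_state_is_noop_on_labels(self):
        trial = _trial([1, 3, 5], canonical=False)
        trial = replace(trial, choice="up")
        out = canonicalize(trial, CounterbalanceState())
        assert [f.aoi for f in out.fixations] == [1, 3, 5]
        assert out.choice == "top" and out.canonical

    def test_row_swap_oracle(self):
        """Oracle: hand-apply the swap to a 3-fixation trial and invert."""
        cb = CounterbalanceState(row_swapped=True)
        trial = replace(_trial([5, 1, 7], canonical=False), choice="up")
        out = canonicalize(trial, cb)
        # screen slots 5,1,7 were displayed swapped: canonical labels 1,5,3
        assert [f.aoi for f in out.fixations] == [1, 5, 3]
        assert out.choice == "bottom"  # pressed "up" on a swapped display

    def test_column_player_transpose_oracle(self):
        """A column player's own payoffs occupy the transposed slots."""
        cb = CounterbalanceState(player_axis="columns")
        trial = replace(_trial([1, 3, 2], canonical=False), choice="left")
        out = canonicalize(trial, cb)
        # slot1 (own, T, L) -> canonical 1; slot3 (own payoff, T, R cell)
        # is the column player's payoff for own action "bottom" vs other "top"
        mapping = canonical_label_map(cb)
        assert [f.aoi for f in out.fixations] == [mapping[1], mapping[3], mapping[2]]
        assert out.choice == "top"  # left column = canonical top action

    @pytest.mark.parametrize("cb", ALL_STATES, ids=str)
    def test_label_map_is_a_bijection(self, cb):
        m = presentation_label_map(cb)
        assert sorted(m) == list(range(1, 9))
        assert sorted(m.values()) == list(range(1, 9))

    @pytest.mark.parametrize("cb", ALL_STATES[::3], ids=str)
    def test_round_trip_through_presentation(self, cb):
        """Mapping canonical labels to presentation slots and canonicalizing
        recovers the original trial exactly."""
        forward = presentation_label_map(cb)
        labels = [1, 4, 6, 7, 2]
        pres = replace(
            _trial([forward[x] for x in labels], canonical=False),
            choice=(
                ("up" if not cb.row_swapped else "down")
                if cb.player_axis == "rows"
                else ("left" if not cb.col_swapped else "right")
            ),
        )
        out = canonicalize(pres, cb)
        assert [f.aoi for f in out.fixations] == labels
        assert out.choice == "top"

    def test_wrong_choice_code_rejected(self):
        trial = replace(_trial([1], canonical=False), choice="left")
        with pytest.raises(ValueError, match="row player"):
            canonicalize(trial, CounterbalanceState(player_axis="rows"))

    def test_double_canonicalization_rejected(self):
        with pytest.raises(ValueError):
            canonicalize(_trial([1], canonical=True))


class TestTransitionTaxonomy:
    @pytest.mark.parametrize(
        "a, b, category",
        [
            (1, 2, "within_cell"),
            (1, 5, "within_column"),
            (1, 3, "within_row"),
            (1, 8, "rare"),
            (1, 4, "rare"),
            (1, 1, "repeat"),
        ],
    )
    def test_named_examples(self, a, b, category):
        assert classify_transition(a, b).category == category

    def test_enumeration_oracle(self):
        """Brute force over all 56 ordered pairs: 24 have exactly one
        attribute change, 32 have two or more."""
        common = rare = 0
        for a, b in itertools.permutations(range(1, 9), 2):
            cls = classify_transition(a, b)
            n_changes = len(cls.changes)
            if n_changes == 1:
                common += 1
                assert cls.category in ("within_cell", "within_column", "within_row")
            else:
                rare += 1
                assert cls.category == "rare"
        assert common == 24 and rare == 32

    @given(st.integers(1, 8), st.integers(1, 8))
    def test_category_matches_changes_invariant(self, a, b):
        cls = classify_transition(a, b)
        if cls.category == "repeat":
            assert cls.changes == frozenset()
        elif cls.category == "rare":
            assert len(cls.changes) >= 2
        else:
            assert len(cls.changes) == 1


class TestTally:
    def test_single_trial_counts(self):
        tally = transition_tally([_trial([1, 3, 1])])
        m = tally.matrix()
        assert m[0, 2] == 1 and m[2, 0] == 1 and tally.total == 2

    def test_trial_contributes_n_minus_1(self):
        labels = [1, 2, 3, 4, 5, 6, 7, 8]
        tally = transition_tally([_trial(labels)])
        assert tally.total == len(labels) - 1

    def test_unlabelled_fixations_break_sequences(self):
        tally = transition_tally([_trial([1, None, 3])])
        assert tally.total == 0

    def test_repeats_collapsed_by_default(self):
        tally = transition_tally([_trial([1, 1, 3])])
        assert tally.total == 1 and tally.repeats == 1

    def test_common_cells_number_24(self):
        from strategaze.transition_model import COMMON_TRANSITIONS

        assert len(COMMON_TRANSITIONS) == 24

    def test_strata_sum_to_unstratified(self):
        trials = [
            _trial([1, 3, 5, 7, 2], choice="top", game="gA"),
            _trial([2, 4, 6, 8, 1], choice="bottom", game="gB", trial_index=1),
            _trial([1, 2, 3], choice="top", game="gA", trial_index=2),
        ]
        plain = transition_tally(trials)
        strat = transition_tally(trials, strata=("half", "choice", "game"))
        assert strat.total == plain.total
        assert np.array_equal(strat.matrix(), plain.matrix())

    def test_half_split_middle_to_second(self):
        # 4 transitions: indices 0,1 -> first half; 2,3 -> second
        tally = transition_tally([_trial([1, 3, 7, 5, 1])], strata=("half",))
        by_half = tally.table.groupby("half")["count"].sum()
        assert by_half["first"] == 2 and by_half["second"] == 2
        # 3 transitions: middle transition goes to the second half
        tally = transition_tally([_trial([1, 3, 7, 5])], strata=("half",))
        by_half = tally.table.groupby("half")["count"].sum()
        assert by_half["first"] == 1 and by_half["second"] == 2

    def test_noncanonical_trials_rejected(self):
        with pytest.raises(ValueError):
            transition_tally([_trial([1, 3], canonical=False)])


class TestGazeBias:
    def test_constructed_terminal_run(self):
        """If the last 30% of fixations always lie on the chosen row, the
        final bin is pure for both choice strata."""
        trials = []
        for i in range(20):
            top_chooser = i % 2 == 0
            run = [1, 3, 2] if top_chooser else [5, 7, 6]
            base = [1, 5, 3, 7, 2, 6, 4]
            trials.append(_trial(
                base + run, choice="top" if top_chooser else "bottom",
                trial_index=i,
            ))
        curve = gaze_bias_curve(trials)
        top_curve = curve[(curve["measure"] == "top") & (curve["choice"] == "top")]
        bot_curve = curve[(curve["measure"] == "top") & (curve["choice"] == "bottom")]
        assert top_curve[top_curve["bin"] == 9]["proportion"].item() == 1.0
        assert bot_curve[bot_curve["bin"] == 9]["proportion"].item() == 0.0

    def test_uniform_gaze_is_flat(self, rng):
        trials = [
            _trial(list(rng.integers(1, 9, size=17)),
                   choice="top" if rng.random() < 0.5 else "bottom",
                   trial_index=i)
            for i in range(400)
        ]
        curve = gaze_bias_curve(trials)
        top = curve[curve["measure"] == "top"]
        se = np.sqrt(0.25 / top["n"])
        assert np.all(np.abs(top["proportion"] - 0.5) < 4 * se)

    def test_zero_label_trials_excluded(self):
        trials = [_trial([None, None]), _trial([1, 3, 5, 7] * 3, trial_index=1)]
        curve = gaze_bias_curve(trials)
        assert curve[curve["measure"] == "top"]["n"].sum() == 12


class TestSummaryStats:
    def test_all_own_trial(self):
        df = summary_stats([_trial([1, 3, 5, 7, 1])])
        row = df[df["participant"] == "p1"].iloc[0]
        assert row["own_fixation_proportion"] == 1.0
        assert row["fixations_per_game"] == 5

    def test_common_share_definition(self):
        # 1->3 common, 3->8 rare, 8->8 repeat (excluded)
        df = summary_stats([_trial([1, 3, 8, 8])])
        row = df[df["participant"] == "pooled"].iloc[0]
        assert row["common_transition_share"] == pytest.approx(0.5)

    def test_duration_round_trip(self, rng):
        durations = rng.lognormal(5.6, 0.3, size=200)
        fixations = tuple(
            _fix(0, 0, onset=float(i), dur=float(d), aoi=1)
            for i, d in enumerate(durations)
        )
        trial = TrialRecord(
            participant="p1", trial_index=0, game_id="g", choice="top",
            rt_ms=1.0, fixations=fixations, canonical=True,
        )
        df = summary_stats([trial])
        row = df.iloc[0]
        assert row["mean_fixation_duration_ms"] == pytest.approx(durations.mean())
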