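import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def game_grid():
    from strategaze.games import default_game_grid

    return default_game_grid()


@pytest.fixture(scope="session")
def game_by_pair(game_grid):
    """First grid game for each (d_left, d_right) pair (base configuration 1)."""
    return {
        (g.d_left, g.d_right): g for g in game_grid if g.base_config == 1
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort_trials():
    """A small mixed canonical cohort shared across model tests:
    8 participants x 64 games, level-k plus accumulator agents."""
    from dataclasses import replace

    from strategaze import gaze as gz
    from strategaze.io import trials_from_logs
    from strategaze.synth import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_participants=8, agent_mix=(0.125, 0.5, 0.25, 0.125), seed=7
    )
    data = generate_cohort(cfg)
    layout = gz.default_layout()
    trials = []
    for t in trials_from_logs(data.fixations, data.choices):
        labelled = gz.assign_fixations(t.fixations, layout)
        trials.append(gz.canonicalize(replace(t, fixations=tuple(labelled))))
    return trials
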