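"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from v1motifs import funcnet, preprocessing, synthetic


@pytest.fixture(scope="session")
def small_schedule():
    # 3 blocks x 8 directions x 2 reps at 20 Hz; short trials keep tests fast
    return synthetic.make_schedule(
        n_blocks=3, n_directions=8, reps_per_block=2,
        grating_dur_s=2.0, grey_dur_s=1.5, frame_rate_hz=20.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_recording(small_schedule):
    cfg = synthetic.SimConfig(n_neurons=16)
    gt, rec = synthetic.simulate_population(cfg, small_schedule, seed=123)
    return gt, rec


@pytest.fixture(scope="session")
def small_dff(small_recording):
    _, rec = small_recording
    return preprocessing.preprocess(rec)


@pytest.fixture(scope="session")
def small_trial_responses(small_dff, small_schedule):
    return preprocessing.trial_means(small_dff, small_schedule)


@pytest.fixture(scope="session")
def small_graph(small_dff, small_schedule, small_recording):
    _, rec = small_recording
    return funcnet.build_functional_graph(
        small_dff, small_schedule, positions_um=rec.positions_um
    )


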