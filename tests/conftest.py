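import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from homefield.behavior import segment_journeys, segment_trials
from homefield.synthetic import BehaviorSpec, FieldSpec, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A 20-trial session with one neuron of each field archetype."""
    fields = {
        "place": FieldSpec(kind="place", place_center=(10.0, 5.0), peak_rate=12.0),
        "leverdist": FieldSpec(kind="lever_distance", peak_rate=14.0,
                               preferred_distance=4.0, distance_sd=3.0),
        "anchored": FieldSpec(kind="lever_anchored", peak_rate=12.0,
                              preferred_direction=60.0, concentration=2.5,
                              drift_slope=0.5, drift_noise_sd=5.0),
    }
    session, truth = generate_session(BehaviorSpec(n_trials=20), fields, seed=101)
    return session, truth


@pytest.fixture(scope="session")
def small_trials(small_session):
    session, _ = small_session
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    return trials


@pytest.fixture(scope="session")
def drift_session():
    """50-trial session with a sharply tuned lever-anchored neuron carrying
    large independent per-trial rotations."""
    fields = {
        "la": FieldSpec(kind="lever_anchored", peak_rate=12.0, concentration=4.0,
                        drift_slope=0.0, drift_noise_sd=28.6)
    }
    session, truth = generate_session(BehaviorSpec(n_trials=50), fields, seed=202)
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    return session, truth, trials


def spike_train(session, neuron_id):
    return next(s.spike_times for s in session.spikes if s.neuron_id == neuron_id)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
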