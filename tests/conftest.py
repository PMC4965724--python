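import numpy as np
import pytest
from hypothesis import settings

import semgrip as sg
from semgrip import evaluation as ev

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def quiet_profile():
    return sg.quiet_profile()


@pytest.fixture(scope="session")
def quiet_hammer_run(quiet_profile):
    """Noise-free, jitter-free hammer-group run: truth equals the schedule."""
    return sg.generate_run(sg.make_schedule("hammer"), quiet_profile, seed=3)


@pytest.fixture(scope="session")
def quiet_hammer_features(quiet_hammer_run):
    bundle = quiet_hammer_run.as_bundle()
    return bundle, sg.compute_mav(bundle), sg.summarize_acc(bundle)


@pytest.fixture(scope="session")
def default_subject_data():
    """One default synthetic subject, fully simulated, featurised and labelled."""
    return ev.build_subject_data(sg.default_profiles()[0], seed=7)


@pytest.fixture(scope="session")
def default_folds(default_subject_data):
    d = default_subject_data
    return ev.make_repetition_folds(d.segments, d.nr_segments)


def truth_labels(mav, truth):
    """Ground-truth label per MAV instance from a truth interval track."""
    labels = np.full(len(mav), "NR", dtype=object)
    for code, a, b in truth:
        sel = (mav.times >= a) & (mav.times < b)
        labels[sel] = code
    return labels.astype(str)
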