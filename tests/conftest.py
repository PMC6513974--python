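import numpy as np
import pytest

import painmap as pm


@pytest.fixture(scope="session")
def reduced_cfg():
    """Reduced-rate generator configuration used throughout the suite."""
    return pm.GeneratorConfig().reduced_rate()


@pytest.fixture(scope="session")
def subject_profile():
    return pm.synth_subject_profile("S000", 42)


@pytest.fixture(scope="session")
def trial_pair(reduced_cfg, subject_profile):
    """A T4 trial plus the subject's pain-free baseline recording."""
    trial = pm.synth_trial(subject_profile, pm.PainLevel.T4, "t4", 1, reduced_cfg)
    base = pm.synth_trial(subject_profile, pm.PainLevel.B, "baseline", 2, reduced_cfg)
    return trial, base


@pytest.fixture(scope="session")
def small_matrix(reduced_cfg):
    """Extracted feature matrix for a small full-factorial roster
    (4 subjects x 5 levels x 4 trials)."""
    roster = pm.make_roster(4, 4, 777)
    return pm.build_feature_matrix(roster, reduced_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
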