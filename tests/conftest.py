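import warnings

import numpy as np
import pytest

import gazefield as gf

# the fuzzy c-means non-convergence warning is informative, not an error
warnings.filterwarnings("ignore", message="fuzzy c-means did not converge")


@pytest.fixture(scope="session")
def geometry():
    return gf.MONOCULAR_SCREEN


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed control/patient cohort small enough for per-test reuse."""
    cfg = gf.CohortConfig(
        n_controls=6, n_patients=6, n_clips=3, clip_duration_s=20.0,
        archetype_mix=("tunnel", "peripheral", "central"), master_seed=7,
    )
    return gf.make_cohort(cfg)


@pytest.fixture(scope="session")
def control_trial():
    """One normal-sighted simulated trial with its ground-truth events."""
    track = gf.make_track(20.0, 0.5, seed=3, clip="clipA")
    fld = gf.make_field("normal", 0.0, noise_sd=0.0)
    rng = np.random.default_rng(11)
    return gf.simulate_trial(track, fld, gf.ObserverModel(), rng, participant="c0")
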