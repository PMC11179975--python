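import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vnssim

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

COHORT_SEED = 20_240_601
COHORT_SIZE = 100


@pytest.fixture(scope="session")
def movement_minimum() -> float:
    """Noise floor calibrated from three seeded rest recordings."""
    recs = []
    for seed in (11, 12, 13):
        rest = vnssim.generate_rest_recording(
            vnssim.SynthConfig(seed=seed, burst_rate=0.0, rest_fraction=0.0)
        )
        recs.append(vnssim.rate_of_change(vnssim.smooth_signal(rest)))
    return vnssim.estimate_movement_minimum(recs)


@pytest.fixture(scope="session")
def default_session(movement_minimum):
    """One seeded default session, preprocessed and gated."""
    raw, annotations = vnssim.generate_session(vnssim.SynthConfig(seed=7))
    roc = vnssim.preprocess(raw, movement_minimum=movement_minimum)
    return raw, roc, annotations


@pytest.fixture(scope="session")
def cohort(movement_minimum):
    """100 seeded default sessions with their dynamic p95 runs (snapshots on)."""
    seeds = np.random.SeedSequence(COHORT_SEED).generate_state(COHORT_SIZE) % (2**31)
    sessions = []
    for seed in seeds:
        raw, _ = vnssim.generate_session(vnssim.SynthConfig(seed=int(seed)))
        roc = vnssim.preprocess(raw, movement_minimum=movement_minimum)
        events, _ = vnssim.run_dynamic(
            roc, vnssim.DynamicParams(percentile=95.0), record_snapshots=True
        )
        sessions.append((roc, events))
    return sessions
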