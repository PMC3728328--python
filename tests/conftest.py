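import dataclasses

import numpy as np
import pytest

from metacage import CohortConfig, SessionConfig, generate_session
from metacage.decomposition import decompose_trace

# a shortened session (07:30 meal-anchored day) that still contains the full
# -120..0 and 0..300 min analysis windows; keeps filter tests fast
SHORT_CLOCK = dict(session_start="07:30", meal_time="10:00", session_end="15:00")


@pytest.fixture
def short_config():
    return SessionConfig(seed=11, **SHORT_CLOCK)


@pytest.fixture
def quiet_config():
    """Deterministic latent state: no drift, no bursts, no analyzer noise."""
    return SessionConfig(
        seed=11,
        rest_ee_walk_sd=0.0,
        rq_walk_sd=0.0,
        activity_burst_rate=0.0,
        noise_sd_vo2=0.0,
        noise_sd_vco2=0.0,
        freeze_gap=0.0,
        **SHORT_CLOCK,
    )


@pytest.fixture
def default_cohort_config():
    return CohortConfig(seed=42)


@pytest.fixture(scope="session")
def decomposed_session():
    """One short HF session run through the full decomposition chain."""
    cfg = SessionConfig(seed=5, meal_type="HF", **SHORT_CLOCK)
    latent, trace = generate_session({"adchg": 2.0}, cfg)
    dec, binned = decompose_trace(trace, tau_s=cfg.tau_s)
    return cfg, latent, trace, dec, binned


def window_mean(binned, column, lo, hi):
    sel = (binned["bin_start_min"] >= lo) & (binned["bin_end_min"] <= hi) & ~binned["flagged"]
    return float(binned.loc[sel, column].mean())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
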