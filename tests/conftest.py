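"""Shared fixtures: seeded synthetic scenarios analysed once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from scalpsd import pipeline, synthetic

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture26():
    """The 26-event similarity fixture: (scalp, ecog, truth)."""
    return synthetic.fixture_26_events(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture26_analyses(fixture26):
    """Full pipeline output on the 26-event fixture (fit once, reuse)."""
    scalp, ecog, truth = fixture26
    sb, eb = synthetic.as_binned(scalp), synthetic.as_binned(ecog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        analyses = pipeline.analyze_events(sb, eb, [ev.t0 for ev in truth])
    return truth, analyses


@pytest.fixture(scope="session")
def single_event_noiseless():
    """One default event, no jitter/noise/drift: (scalp, ecog, truth)."""
    cfg = synthetic.ScenarioConfig(
        n_events=1, jitter=False, noise_frac=0.0, noise_floor_uv=0.0,
        drift=False, seed=0,
    )
    return synthetic.generate_scenario(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
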