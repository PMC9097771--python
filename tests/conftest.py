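"""Shared fixtures: one small synthetic session and its encoding model.

All fixtures are generated programmatically at test time; nothing is
stored on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import goalreplay as gr
from goalreplay.behavior import compute_velocity
from goalreplay.decoder import EncodingModel
from goalreplay.maps import build_rate_map
from goalreplay.synthetic import SessionConfig, TrajectoryParams


@pytest.fixture(scope="session")
def small_session() -> gr.SessionData:
    """A compact session: 60 units, 14 trials, deterministic seed."""
    cfg = SessionConfig(n_units=60, trajectory=TrajectoryParams(n_trials=14))
    return gr.generate_session(cfg, seed=3)


@pytest.fixture(scope="session")
def large_session() -> gr.SessionData:
    """A ~10-minute session with 120 units at default rates."""
    cfg = SessionConfig(n_units=120, trajectory=TrajectoryParams(n_trials=50))
    return gr.generate_session(cfg, seed=17)


@pytest.fixture(scope="session")
def large_model(large_session):
    """(EncodingModel, place-cell spikes, speed) for the large session."""
    speed = compute_velocity(large_session.position)
    maps, ids = [], []
    for u in range(large_session.n_units):
        rm = build_rate_map(large_session.spikes[u], large_session.position,
                            large_session.arena, speed=speed)
        if large_session.unit_class[u] == "excitatory" and rm.peak_rate > 1:
            maps.append(rm)
            ids.append(u)
    model = EncodingModel.from_rate_maps(maps, np.asarray(ids))
    spikes = [large_session.spikes[u] for u in ids]
    return model, spikes, speed


@pytest.fixture(scope="session")
def small_speed(small_session) -> np.ndarray:
    return compute_velocity(small_session.position)


@pytest.fixture(scope="session")
def small_model(small_session, small_speed):
    """(EncodingModel, place-cell spike trains, place-cell unit ids)."""
    maps, ids = [], []
    for u in range(small_session.n_units):
        rm = build_rate_map(small_session.spikes[u], small_session.position,
                            small_session.arena, speed=small_speed)
        if small_session.unit_class[u] == "excitatory" and rm.peak_rate > 1:
            maps.append(rm)
            ids.append(u)
    model = EncodingModel.from_rate_maps(maps, np.asarray(ids))
    spikes = [small_session.spikes[u] for u in ids]
    return model, spikes, ids
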