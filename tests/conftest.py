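"""Shared fixtures: small trace configs and a cache of processed preset runs.

Full preset pipelines (simulate -> filter -> detect) cost ~1 s each, so runs
are memoised per (preset, replicate) for the whole session and shared
between the signal-processing, gating and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from impedcyto.sigproc import process_trace
from impedcyto.synth import TraceConfig, preset_config, preset_sample

# distinct seed banks per sample so the three "experiments" are independent
PRESET_SEED_BASE = {"pure_beads": 0, "pure_cells": 100, "mixture": 200}
N_REPLICATES = 10


@dataclass
class PresetRun:
    preset: str
    seed: int
    log: pd.DataFrame  # ground truth
    events: pd.DataFrame  # detected
    noise_sigmas: dict[float, float]


@pytest.fixture(scope="session")
def preset_run():
    """Callable fixture: ``preset_run(name, replicate)`` -> :class:`PresetRun`."""
    cache: dict[tuple[str, int], PresetRun] = {}

    def get(preset: str, replicate: int = 0) -> PresetRun:
        key = (preset, replicate)
        if key not in cache:
            seed = PRESET_SEED_BASE[preset] + replicate
            trace, log = preset_sample(preset, seed)
            events, _, sigmas = process_trace(trace)
            cache[key] = PresetRun(
                preset=preset, seed=seed, log=log, events=events, noise_sigmas=sigmas
            )
        return cache[key]

    return get


@pytest.fixture()
def small_config() -> TraceConfig:
    """A short trace for fast unit tests (4 s, 40 events)."""
    return TraceConfig(duration_s=4.0, n_events=40, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def preset_truth_count(preset: str) -> int:
    return preset_config(preset, 0).n_events
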