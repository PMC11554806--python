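"""Shared fixtures: default apparatus/registry and simulated cohorts.

Simulation-backed fixtures are module-scoped so the CTMC runs once per
session per configuration; everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from habsoc import (
    Animal,
    AnimalRegistry,
    Apparatus,
    ProtocolWindows,
    SimConfig,
    reconstruct_visits,
    simulate_habitat,
)


@pytest.fixture(scope="session")
def apparatus() -> Apparatus:
    return Apparatus()


@pytest.fixture(scope="session")
def registry() -> AnimalRegistry:
    return AnimalRegistry(
        [
            Animal("m00", "TAG0000", "WT", "M"),
            Animal("m01", "TAG0001", "HET", "M"),
            Animal("m02", "TAG0002", "MUT", "M"),
        ]
    )


@pytest.fixture(scope="session")
def protocol() -> ProtocolWindows:
    return ProtocolWindows()


@pytest.fixture(scope="session")
def sim_lossless(apparatus):
    """10-animal, 84-h cohort at perfect detection, with reconstruction."""
    config = SimConfig(n_animals=10, seed=7, alpha=0.0, p_det=1.0)
    events, truth = simulate_habitat(config)
    visits, repairs = reconstruct_visits(
        events, apparatus, truth.registry,
        session_end=config.protocol().duration_s,
    )
    return config, events, truth, visits, repairs


def discretized_budget(visits: pd.DataFrame, animal: str,
                       window: tuple[float, float]) -> np.ndarray:
    """Independent 1-s timeline oracle for compartment time budgets."""
    w0, w1 = window
    grid = np.arange(w0, w1, 1.0) + 0.5
    comp = compartment_at(visits[visits["animal"] == animal], grid)
    n = grid.size
    return np.array([(comp == c).sum() / n for c in (1, 2, 3, 4)])


def compartment_at(visits_one: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Compartment occupied at each time (0 = transit/unassigned)."""
    starts = visits_one["start_s"].to_numpy()
    ends = visits_one["end_s"].to_numpy()
    comps = visits_one["compartment"].to_numpy()
    order = np.argsort(starts)
    starts, ends, comps = starts[order], ends[order], comps[order]
    idx = np.searchsorted(starts, times, side="right") - 1
    out = np.zeros(times.size, dtype=int)
    ok = idx >= 0
    inside = np.zeros_like(ok)
    inside[ok] = times[ok] < ends[idx[ok]]
    out[inside] = comps[idx[inside]]
    return out
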