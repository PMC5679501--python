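"""Shared fixtures and simulation helpers for the test suite."""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from mirpair import CtMatrix, aggregate_replicates, apply_detection_limit
from mirpair import simulate as sim


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_matrix(columns: dict, sample_ids=None, **kwargs) -> CtMatrix:
    """Build a CtMatrix from {mirna: values} columns."""
    frame = pd.DataFrame(columns, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(len(frame))]
    frame.index = pd.Index(sample_ids, name="sample_id")
    return CtMatrix(frame, **kwargs)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, deterministic given seed."""
    return [int(c.generate_state(1)[0] % (2**31))
            for c in np.random.SeedSequence(seed).spawn(n)]


def simulate_matrix(cfg: sim.SyntheticConfig, seed: int | None = None):
    """Simulate a cohort and return (masked CtMatrix, metadata indexed by id)."""
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    replicates, meta, truth = sim.simulate_cohort(cfg)
    matrix = apply_detection_limit(
        aggregate_replicates(replicates, cfg.detection_limit))
    return matrix, meta.set_index("sample_id"), truth


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    """Silence sklearn deprecation chatter so test output stays readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning,
                                module="sklearn")
        yield
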