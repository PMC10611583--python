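"""Shared fixtures: desk-scale pipeline runs reused across the suite.

The multi-seed pipeline runs are the expensive part of the suite; they are
computed once per session and shared by the recovery, coverage, null and
validation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fcgroups.pipeline import desk_config, run_pipeline

RECOVERY_SEEDS = tuple(range(1, 11))
NULL_SEEDS = tuple(range(1, 11))


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full pipeline on the default planted cohort, one run per master seed."""
    return {seed: run_pipeline(desk_config(seed=seed)) for seed in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def null_runs():
    """Full pipeline on structure-free cohorts (delta = delta_bold = 0)."""
    runs = {}
    for seed in NULL_SEEDS:
        cfg = desk_config(seed=seed)
        cfg.sim.delta = 0.0
        cfg.sim.delta_bold = 0.0
        runs[seed] = run_pipeline(cfg)
    return runs


@pytest.fixture(scope="session")
def one_run(pipeline_runs):
    """A single representative pipeline run."""
    return pipeline_runs[RECOVERY_SEEDS[0]]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
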