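"""Shared fixtures: small seeded synthetic sessions reused across tests.

Session-scoped so the expensive EMG synthesis runs once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from hdsemg import pipeline
from hdsemg.movement_labels import default_table


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions: 4 movements x 2 repetitions with the
    default 5 s hold / 5 s rest schedule, two failing contacts."""
    return pipeline.PipelineConfig(
        n_movements=4, n_reps=2, seed=2024, n_bad_channels=2
    )


@pytest.fixture(scope="session")
def small_raw(small_config):
    return pipeline.run_simulate(small_config)


@pytest.fixture(scope="session")
def small_result(small_raw, small_config):
    return pipeline.run_process(small_raw, small_config)
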