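"""Shared fixtures: a compact simulated study reused across tests.

The `small_run` fixture executes the whole discovery funnel once on a
reduced synthetic study (3 alien chromosomes of 120 kb) so that
integration-level tests can interrogate a single result; unit tests build
their own tiny inputs.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from alienmark import PipelineConfig, SimulationConfig, run_pipeline


def random_dna(n: int, seed: int | None = None, rng: random.Random | None = None) -> str:
    rng = rng or random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(
        simulation=SimulationConfig(
            seed=7,
            n_alien_chromosomes=3,
            chromosome_length=120_000,
            alien_specific_region_rate=70.0,
            alien_specific_region_length=(3_000, 5_000),
        )
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    return run_pipeline(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
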