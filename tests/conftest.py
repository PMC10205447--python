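"""Shared fixtures: a small toy world and a mid-scale full pipeline run.

Everything is generated programmatically at test time; the mid-scale run
(10 zones, ~1000 persons each) is session-scoped and shared by the
end-to-end checks to keep the suite fast.
"""

import numpy as np
import pytest

from mobisynth.config import Config
from mobisynth import fixtures, pipeline


def tiny_config(seed: int = 0) -> Config:
    cfg = Config()
    cfg.world.n_municipalities = 1
    cfg.world.zones_per_municipality = 3
    cfg.world.persons_per_zone_range = (700, 900)
    cfg.world.survey_size = 400
    cfg.world.seed = seed
    return cfg


def midscale_config() -> Config:
    cfg = Config()
    cfg.world.n_municipalities = 2
    cfg.world.zones_per_municipality = 5
    cfg.world.persons_per_zone_range = (950, 1050)
    cfg.world.survey_size = 2000
    return cfg


@pytest.fixture(scope="session")
def small_world():
    """A 3-zone world with survey, OD matrices and trips."""
    return fixtures.generate_full_world(tiny_config().world, n_trips_per_cell=200)


@pytest.fixture(scope="session")
def midscale_result() -> pipeline.PipelineResult:
    """Full pipeline on 10 zones x ~1000 persons (about 10k agents)."""
    return pipeline.run_all(midscale_config(), seed=3, n_trips_per_cell=500)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
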