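import numpy as np
import pytest

from gliocam.config import (CohortSection, CropSection, PipelineConfig,
                            TrainSection)
from gliocam.io_formats import VolumeGrid
from gliocam.pipeline import run_pipeline
from gliocam.synthetic_data import CohortSpec, make_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_grid():
    return VolumeGrid(shape=(24, 24, 12))


@pytest.fixture
def tiny_atlas(tiny_grid):
    return make_atlas(tiny_grid, n_regions=4, seed=7)


@pytest.fixture
def tiny_spec(tiny_grid):
    return CohortSpec(n_short=2, n_medium=2, n_long=2, grid=tiny_grid,
                      n_regions=4, seed=11, tumor_radius_frac=0.16)


def _mini_config() -> PipelineConfig:
    """A fast, small-but-complete pipeline configuration for integration
    tests (not the study conditions)."""
    cfg = PipelineConfig()
    cfg.cohort = CohortSection(n_short=4, n_medium=3, n_long=5,
                               grid_shape=(32, 32, 16), n_regions=6)
    cfg.crop = CropSection(n_inferior=2, n_superior=2)
    cfg.train = TrainSection(max_epochs=6, learning_rate=3e-3, augment=False)
    cfg.seed = 3
    return cfg


@pytest.fixture(scope="session")
def mini_state(tmp_path_factory):
    """Small end-to-end pipeline run shared by integration tests."""
    out = tmp_path_factory.mktemp("mini_run")
    return run_pipeline(_mini_config(), out), out


@pytest.fixture(scope="session")
def study_state(tmp_path_factory):
    """Full desk-scale pipeline run under the default study conditions."""
    out = tmp_path_factory.mktemp("study_run")
    cfg = PipelineConfig()
    cfg.seed = 1
    return run_pipeline(cfg, out), out
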