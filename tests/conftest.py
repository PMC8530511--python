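import numpy as np
import pytest

from rpemorph.grid import SegmentationMask, VoxelGrid
from rpemorph.phantom import flattening_trajectory_spec
from rpemorph.pipeline import PipelineResult, RunConfig, run_pipeline


@pytest.fixture(scope="session")
def flattening_run() -> PipelineResult:
    """Full pipeline on the canonical flattening trajectory (noise + ramp on)."""
    return run_pipeline(RunConfig(phantom=flattening_trajectory_spec(seed=1)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_grid(values, spacing=(1.0, 1.0, 1.0), **kw) -> VoxelGrid:
    return VoxelGrid(np.asarray(values, dtype=float), spacing, **kw)


def make_mask(values, spacing=(1.0, 1.0, 1.0), **kw) -> SegmentationMask:
    return SegmentationMask(np.asarray(values, dtype=bool), spacing, **kw)
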