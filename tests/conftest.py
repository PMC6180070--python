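import pytest

from mwmtsa import (ArenaGeometry, CohortSpec, SegmentationConfig,
                    generate_cohort)
from mwmtsa.segmentation import segment_cohort


@pytest.fixture(scope="session")
def arena() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture(scope="session")
def small_cohort(arena):
    """A compact two-group cohort shared by the slower integration tests."""
    spec = CohortSpec(group_sizes={"stress": 4, "control": 4}, seed=3)
    return generate_cohort(spec, arena)


@pytest.fixture(scope="session")
def small_segments(small_cohort, arena):
    trajs, truth = small_cohort
    segments, short = segment_cohort(trajs, SegmentationConfig(250.0, 0.70))
    return segments, short, truth
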