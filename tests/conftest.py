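import numpy as np
import pytest

from corneatopo.config import PipelineConfig
from corneatopo.pipeline import process_frame
from corneatopo.segmentation import CenterLine, SegmentationResult
from corneatopo.synthetic import GroundTruth, SyntheticConfig, make_frame


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def rest_frame():
    """Default-geometry rest frame with mild noise, plus its ground truth."""
    config = SyntheticConfig(noise_sigma=0.01)
    frame, gt = make_frame(config, 0)
    return config, frame, gt


@pytest.fixture(scope="session")
def rest_segmentation(rest_frame, pipeline_config):
    """Segmentation + curvature of the rest frame (shared; expensive)."""
    _, frame, _ = rest_frame
    return process_frame(frame, pipeline_config)


@pytest.fixture(scope="session")
def concave_frame():
    """Frame at highest concavity with its ground truth."""
    config = SyntheticConfig(noise_sigma=0.01)
    frame, gt = make_frame(config, config.concavity_frame)
    return config, frame, gt


@pytest.fixture(scope="session")
def concave_segmentation(concave_frame, pipeline_config):
    _, frame, _ = concave_frame
    return process_frame(frame, pipeline_config)


def central_band(n_cols: int) -> slice:
    """The central two-thirds of the columns, where accuracy is asserted."""
    return slice(n_cols // 6, n_cols - n_cols // 6)


def seg_from_truth(gt: GroundTruth) -> SegmentationResult:
    """Wrap analytic ground-truth boundaries as a segmentation result."""
    n = len(gt.upper_rows)
    valid = np.ones(n, dtype=bool)
    center = CenterLine(
        raw_rows=gt.center_rows.copy(),
        raw_intensity=np.ones(n),
        poly_coeffs=np.zeros(6),
        fitted_rows=gt.center_rows.copy(),
        valid_cols=valid,
    )
    return SegmentationResult(
        center=center,
        upper_rows=gt.upper_rows.copy(),
        lower_rows=gt.lower_rows.copy(),
        upper_valid=valid.copy(),
        lower_valid=valid.copy(),
        quality_flags=np.zeros(n, dtype=bool),
    )
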