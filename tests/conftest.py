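import numpy as np
import pytest

from nucseg.evaluate import masks_from_label_map, match_and_score
from nucseg.pipeline import PipelineConfig, segment_image
from nucseg.synthetic import generate_nuclei_image, preset_spec


@pytest.fixture(scope="session")
def small_easy_tile():
    """Small well-separated tile used by several end-to-end unit tests."""
    spec = preset_spec("easy", seed=11, n_nuclei=8, size=(256, 256))
    return generate_nuclei_image(spec)


@pytest.fixture(scope="session")
def small_easy_result(small_easy_tile):
    return segment_image(small_easy_tile.rgb)


def score_tile(tile, cfg: PipelineConfig | None = None):
    """Segment one synthetic tile and score it against its ground truth."""
    result = segment_image(tile.rgb, cfg)
    gt = masks_from_label_map(tile.labels)
    return match_and_score(gt, result.pixel_sets(), tile.labels.shape), result
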