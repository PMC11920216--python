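from __future__ import annotations

import numpy as np
import pytest

from fixscore.grid import TrackingGrid
from fixscore.ingest import MARK_RGB
from fixscore.metrics import AnxietyClass
from fixscore.synthetic import HR_TIME_POINTS, GroundTruth, SyntheticConfig


@pytest.fixture
def grid() -> TrackingGrid:
    """A 6 x 6 mm tracking square at 50 px/mm, crosshair at (175, 175)."""
    return TrackingGrid(center_px=(175, 175), px_per_mm=50.0)


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_per_class=4, seed=11)


def render_squares(
    grid: TrackingGrid, squares: list[tuple[int, int, int]], size: int = 351
) -> np.ndarray:
    """Minimal plot image: white background with blue squares at (row, col, side)."""
    img = np.full((size, size, 3), 255, dtype=np.uint8)
    for row, col, side in squares:
        img[row : row + side, col : col + side] = MARK_RGB
    return img


def make_truth(
    grid: TrackingGrid,
    origins: list[tuple[int, int]],
    side: int = 5,
    eye_side: str = "right",
) -> GroundTruth:
    """Ground truth with the given geometry and placeholder metadata."""
    return GroundTruth(
        subject_id="t-0000",
        anxiety_class=AnxietyClass.NORMAL,
        eye_side=eye_side,
        square_origins=list(origins),
        mark_side_px=side,
        grid=grid,
        hads_items=(0, 0, 0, 0, 0, 0, 0),
        vas=1,
        heart_rate={tp: 65.0 for tp in HR_TIME_POINTS},
        break_count=0,
        break_duration_s=0.0,
    )
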