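"""Class-wise average pupil-center position maps.

Averaging the binary mark masks of all subjects in an anxiety class yields a
per-pixel frequency map: the fraction of subjects whose pupil center was
recorded at each location.  Lighter (higher) areas are the commonly spotted
positions; the map's area-weighted centroid offset from the crosshair
summarizes the systematic decentration (nasal/upward in real cohorts).

Plain frequency averaging is the primary estimator.  An optional PCA route
projects the mask stack onto its top-k principal components before
averaging — a denoised interpretation of the same map, clearly secondary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.decomposition import PCA

from .grid import TrackingGrid
from .ingest import MarkMask


@dataclass
class AverageMap:
    """Per-pixel mark frequency across the subjects of one class/eye side."""

    frequency: np.ndarray  # float in [0, 1]
    class_label: str
    eye_side: str
    n_subjects: int
    grid: TrackingGrid
    centroid_offset: tuple[float, float]  # (dx, dy) px from grid center

    @property
    def support_area(self) -> int:
        """Number of pixels touched by at least one subject."""
        return int(np.count_nonzero(self.frequency > 0))


def _centroid_offset(frequency: np.ndarray, grid: TrackingGrid) -> tuple[float, float]:
    total = frequency.sum()
    if total == 0:
        return (0.0, 0.0)
    rows, cols = np.nonzero(frequency)
    w = frequency[rows, cols]
    cx, cy = grid.center_px
    dx = float((w * cols).sum() / total - cx)
    dy = float((w * rows).sum() / total - cy)
    return (dx, dy)


def _check_masks(masks: list[MarkMask]) -> None:
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].mask.shape
    grid = masks[0].grid
    for m in masks[1:]:
        if m.mask.shape != shape or m.grid != grid:
            raise ValueError("all masks must share image shape and grid geometry")


def average_class_map(
    masks: list[MarkMask], class_label: str, eye_side: str = "all"
) -> AverageMap:
    """Mean of binary masks: per-pixel fraction of subjects with a mark there."""
    _check_masks(masks)
    stack = np.stack([m.mask for m in masks]).astype(float)
    freq = stack.mean(axis=0)
    return AverageMap(
        frequency=freq,
        class_label=class_label,
        eye_side=eye_side,
        n_subjects=len(masks),
        grid=masks[0].grid,
        centroid_offset=_centroid_offset(freq, masks[0].grid),
    )


def pca_denoise(
    masks: list[MarkMask], k: int, class_label: str, eye_side: str = "all"
) -> AverageMap:
    """Average map after projecting the mask stack onto k principal components.

    ``k = 0`` keeps only the centering term (the plain mean image); full-rank
    ``k`` reproduces :func:`average_class_map` up to numerical tolerance.
    Reconstructions are clipped to [0, 1] before averaging.
    """
    _check_masks(masks)
    n = len(masks)
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of masks ({n})")
    shape = masks[0].mask.shape
    flat = np.stack([m.mask.ravel() for m in masks]).astype(float)
    if k == 0:
        recon = np.tile(flat.mean(axis=0), (n, 1))
    else:
        pca = PCA(n_components=k, svd_solver="full")
        recon = pca.inverse_transform(pca.fit_transform(flat))
    recon = np.clip(recon, 0.0, 1.0)
    freq = recon.mean(axis=0).reshape(shape)
    return AverageMap(
        frequency=freq,
        class_label=class_label,
        eye_side=eye_side,
        n_subjects=n,
        grid=masks[0].grid,
        centroid_offset=_centroid_offset(freq, masks[0].grid),
    )


def pca_reconstruction_error(masks: list[MarkMask], k: int) -> float:
    """Mean squared reconstruction error of the stack at k components."""
    _check_masks(masks)
    flat = np.stack([m.mask.ravel() for m in masks]).astype(float)
    if k == 0:
        recon = np.tile(flat.mean(axis=0), (len(masks), 1))
    else:
        pca = PCA(n_components=k, svd_solver="full")
        recon = pca.inverse_transform(pca.fit_transform(flat))
    return float(np.mean((flat - recon) ** 2))


def save_map_png(avg_map: AverageMap, path: str | Path) -> None:
    """Write the frequency raster as a lossless 16-bit grayscale PNG."""
    scaled = np.round(avg_map.frequency * 65535).astype(np.uint16)
    Image.fromarray(scaled, mode="I;16").save(path, format="PNG")


def maps_summary_frame(maps: list[AverageMap]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": m.class_label,
                "eye_side": m.eye_side,
                "n_subjects": m.n_subjects,
                "support_area_px": m.support_area,
                "centroid_offset_x_px": m.centroid_offset[0],
                "centroid_offset_y_px": m.centroid_offset[1],
            }
            for m in maps
        ]
    )
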