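"""Decode pupil-center plot images into mark masks and connected clusters.

The device plot marks every sampled pupil-center position with a small blue
square; overlapping squares merge into connected blobs.  This module turns a
raster plot into (1) a binary :class:`MarkMask` of mark pixels inside the
tracking square and (2) a :class:`ClusterSet` of connected components with
the per-cluster measurements (pixel area, boundary-edge perimeter, centroid,
distance to the grid center) that feed the fixation-instability metrics.

Mark detection is a configurable hue/saturation/value band defaulting to
saturated blue; gridlines, axes and the fixation crosshair of real plots are
excluded by the band, and any matching pixel outside the tracking square is
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops
from skimage.transform import resize

from .grid import TrackingGrid


@dataclass(frozen=True)
class ColorSpec:
    """Hue/saturation/value band identifying mark pixels.

    Hue is on the [0, 1) circle (blue ~ 2/3).  Defaults select saturated
    blue; both bounds of each channel are inclusive.
    """

    hue_range: tuple[float, float] = (0.55, 0.78)
    min_saturation: float = 0.5
    min_value: float = 0.2

    def match(self, rgb: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside the band for an RGB float/uint8 image."""
        arr = np.asarray(rgb)
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError("expected a 3-channel RGB raster")
        hsv = rgb2hsv(arr[..., :3])
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        lo, hi = self.hue_range
        if lo <= hi:
            hue_ok = (h >= lo) & (h <= hi)
        else:  # band wrapping the hue circle
            hue_ok = (h >= lo) | (h <= hi)
        return hue_ok & (s >= self.min_saturation) & (v >= self.min_value)


DEFAULT_COLOR_SPEC = ColorSpec()
#: Pure RGB blue; the synthetic renderer draws marks in this color, which sits
#: at the center of the default detection band.
MARK_RGB = (0, 0, 255)


@dataclass
class MarkMask:
    """Binary raster of detected pupil-center marks within the tracking grid."""

    mask: np.ndarray
    grid: TrackingGrid
    source_id: str = ""
    empty_warning: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_mark_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Cluster:
    """One connected component of mark pixels."""

    pixel_area: int
    perimeter: float
    centroid_px: tuple[float, float]  # (x, y) image coordinates
    distance_to_center: float

    def __post_init__(self) -> None:
        if self.pixel_area < 1:
            raise ValueError("pixel_area must be >= 1")
        if self.perimeter < 4:
            raise ValueError("edge-count perimeter of any cluster is >= 4")
        if self.distance_to_center < 0:
            raise ValueError("distance_to_center must be >= 0")


@dataclass
class ClusterSet:
    """Connected clusters partitioning a mark mask."""

    clusters: list[Cluster]
    grid: TrackingGrid
    union_area: int = field(default=0)

    def __post_init__(self) -> None:
        total = sum(c.pixel_area for c in self.clusters)
        if self.union_area == 0:
            self.union_area = total
        elif self.union_area != total:
            raise ValueError(
                "clusters must partition the mask: union_area "
                f"{self.union_area} != sum of cluster areas {total}"
            )

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": range(len(self.clusters)),
                "area_px": [c.pixel_area for c in self.clusters],
                "perimeter_px": [c.perimeter for c in self.clusters],
                "centroid_x_px": [c.centroid_px[0] for c in self.clusters],
                "centroid_y_px": [c.centroid_px[1] for c in self.clusters],
                "dist_px": [c.distance_to_center for c in self.clusters],
            }
        )


def edge_perimeter(binary: np.ndarray) -> int:
    """Boundary-edge count of a binary blob.

    Counts pixel edges separating foreground from background or the image
    border (city-block contour): a single pixel has perimeter 4 and an
    ``s`` x ``s`` square has perimeter ``4 s``.
    """
    m = np.asarray(binary, dtype=bool)
    n = int(m.sum())
    horiz = int(np.count_nonzero(m[:, 1:] & m[:, :-1]))
    vert = int(np.count_nonzero(m[1:, :] & m[:-1, :]))
    return 4 * n - 2 * (horiz + vert)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF plot into an RGB uint8 array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise ValueError(f"cannot decode image {path!r}: {exc}") from exc


def rescale_to_reference(
    image: np.ndarray, grid: TrackingGrid, reference_px_per_mm: float
) -> tuple[np.ndarray, TrackingGrid]:
    """Resample a plot so measurements are made at the reference resolution.

    Nearest-neighbour interpolation keeps mark colors inside the detection
    band.  Returns the resampled image and the rescaled grid.
    """
    factor = reference_px_per_mm / grid.px_per_mm
    if abs(factor - 1.0) < 1e-12:
        return image, grid
    h, w = image.shape[:2]
    out_shape = (max(1, round(h * factor)), max(1, round(w * factor)))
    resampled = resize(
        image, out_shape, order=0, preserve_range=True, anti_aliasing=False
    ).astype(image.dtype)
    new_grid = TrackingGrid(
        center_px=(grid.center_px[0] * factor, grid.center_px[1] * factor),
        px_per_mm=reference_px_per_mm,
        extent_mm=grid.extent_mm,
    )
    return resampled, new_grid


def detect_marks(
    image: np.ndarray | str | Path,
    grid: TrackingGrid,
    color_spec: ColorSpec = DEFAULT_COLOR_SPEC,
    source_id: str = "",
) -> MarkMask:
    """Detect pupil-center mark pixels inside the tracking square.

    Pixels matching the color band outside the tracking square (axis labels,
    legend swatches) are discarded.  An empty plot is valid: the returned
    mask carries ``empty_warning=True`` and a ``UserWarning`` is emitted.
    """
    if not isinstance(image, np.ndarray):
        image = load_image(image)
    grid.validate_in_image(image.shape)
    raw = color_spec.match(image)

    r0, r1, c0, c1 = grid.bounds_px()
    window = np.zeros_like(raw)
    rr0, rr1 = max(r0, 0), min(r1, raw.shape[0] - 1)
    cc0, cc1 = max(c0, 0), min(c1, raw.shape[1] - 1)
    window[rr0 : rr1 + 1, cc0 : cc1 + 1] = True
    mask = raw & window

    empty = not mask.any()
    if empty:
        warnings.warn(
            f"no mark pixels detected in plot {source_id!r}; "
            "treating as an empty (perfectly stable) plot",
            UserWarning,
            stacklevel=2,
        )
    return MarkMask(mask=mask, grid=grid, source_id=source_id, empty_warning=empty)


def extract_clusters(mark_mask: MarkMask, connectivity: int = 2) -> ClusterSet:
    """Group mark pixels into connected clusters and measure each one.

    Components use 8-connectivity by default (``connectivity=2``; diagonal
    contact merges clusters, matching how overlapping mark squares read
    visually); pass ``connectivity=1`` for 4-connectivity.  Per cluster the
    pixel area, boundary-edge perimeter, unweighted pixel-centroid and the
    Euclidean centroid distance to the grid center are computed.
    """
    mask = mark_mask.mask
    if not mask.any():
        return ClusterSet(clusters=[], grid=mark_mask.grid, union_area=0)

    labels = label(mask, connectivity=connectivity)
    cx, cy = mark_mask.grid.center_px
    clusters: list[Cluster] = []
    for region in regionprops(labels):
        rmin, cmin, rmax, cmax = region.bbox
        blob = labels[rmin:rmax, cmin:cmax] == region.label
        perim = edge_perimeter(blob)
        # centroid as the unweighted mean of member pixels; computed from the
        # pixel coordinates directly so it is reproducible bit-for-bit from
        # the pixel set alone
        rows, cols = np.nonzero(blob)
        crow = rows.mean() + rmin
        ccol = cols.mean() + cmin
        dist = float(np.hypot(ccol - cx, crow - cy))
        clusters.append(
            Cluster(
                pixel_area=int(rows.size),
                perimeter=float(perim),
                centroid_px=(float(ccol), float(crow)),
                distance_to_center=dist,
            )
        )
    return ClusterSet(
        clusters=clusters, grid=mark_mask.grid, union_area=int(mask.sum())
    )


def save_mask_png(mark_mask: MarkMask, path: str | Path) -> None:
    """Write a mark mask as a lossless 8-bit PNG (255 = mark)."""
    Image.fromarray((mark_mask.mask * np.uint8(255))).save(path, format="PNG")


def load_mask_png(path: str | Path, grid: TrackingGrid, source_id: str = "") -> MarkMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L")) > 127
    return MarkMask(mask=arr, grid=grid, source_id=source_id)


def save_clusters_csv(cluster_set: ClusterSet, path: str | Path) -> None:
    cluster_set.to_frame().to_csv(path, index=False)


def read_sidecar(path: str | Path) -> pd.DataFrame:
    """Read a per-image sidecar table (CSV) of grid geometry and identity.

    Required columns: ``image``, ``center_x_px``, ``center_y_px``,
    ``px_per_mm``; optional: ``eye_side``, ``subject_id``.
    """
    df = pd.read_csv(path)
    required = {"image", "center_x_px", "center_y_px", "px_per_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sidecar {path} missing columns: {sorted(missing)}")
    return df
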