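"""Tracking-grid geometry for eye-tracker pupil-center plots.

The excimer-laser eye tracker reports pupil-center offsets inside a square
tracking area of 6 x 6 mm (3 mm above/below and 3 mm temporal/nasal of the
fixation crosshair).  All plot measurements in this package are made in
pixel units at a fixed reference resolution; the grid object carries the
pixel location of the crosshair and the pixel/mm scale needed to map between
the two.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_EXTENT_MM = 3.0
#: Reference plot resolution at which SA/SP/ACD are expressed (pixels per mm).
REFERENCE_PX_PER_MM = 50.0


@dataclass(frozen=True)
class TrackingGrid:
    """Geometry of the 6 x 6 mm tracking square within a plot image.

    Parameters
    ----------
    center_px
        ``(x, y)`` pixel coordinate of the crosshair center (column, row).
    px_per_mm
        Plot scale in pixels per millimetre.
    extent_mm
        Half-width of the tracking square in millimetres (3.0 for the
        6 x 6 mm area).
    """

    center_px: tuple[float, float]
    px_per_mm: float = REFERENCE_PX_PER_MM
    extent_mm: float = DEFAULT_EXTENT_MM

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if self.center_px[0] < 0 or self.center_px[1] < 0:
            raise ValueError("center_px must be non-negative image coordinates")

    @property
    def half_extent_px(self) -> int:
        """Half-width of the tracking square in (rounded) pixels."""
        return int(round(self.extent_mm * self.px_per_mm))

    def bounds_px(self) -> tuple[int, int, int, int]:
        """Inclusive pixel bounds of the tracking square.

        Returns ``(row_min, row_max, col_min, col_max)``.
        """
        cx, cy = self.center_px
        h = self.half_extent_px
        return (
            int(round(cy)) - h,
            int(round(cy)) + h,
            int(round(cx)) - h,
            int(round(cx)) + h,
        )

    def contains_px(self, row: int, col: int) -> bool:
        r0, r1, c0, c1 = self.bounds_px()
        return r0 <= row <= r1 and c0 <= col <= c1

    def validate_in_image(self, shape: tuple[int, ...]) -> None:
        """Raise if the crosshair center lies outside an image of ``shape``."""
        h, w = shape[:2]
        cx, cy = self.center_px
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(
                f"grid center {self.center_px} outside image of shape {(h, w)}"
            )
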