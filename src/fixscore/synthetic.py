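"""Class-conditional synthetic pupil-center plots with analytic ground truth.

Real plots and their clinical metadata are not openly available, so every
downstream stage is exercised on synthetic cohorts.  Per subject the
generator draws a set of dwell positions — independent isotropic Gaussian
scatter around a class-dependent bias vector, truncated to the tracking
square — and renders each dwell as a small blue square, exactly as the
device plot does.  Dispersion, bias magnitude and dwell count all grow with
anxiety class (normal < borderline < case), emulating the progressive
increase of decentration area across classes, with default magnitudes chosen
so cohort medians of SA/SP/ACD land in the order-of-magnitude ranges seen on
the real device at the 50 px/mm reference scale.

The model is deliberately spatial-only: the device plot discards time
ordering, so a time-correlated trajectory would add nothing the measured
parameters can see.  Saccade dynamics, microsaccades, cyclotorsion and
tracker latency are out of scope.

Ground truth carries the exact square coordinates, so (SA, SP, ACD) can be
computed by direct pixel enumeration of the square-union geometry —
independent of the render -> detect -> cluster image pathway — plus
correlated metadata: HADS anxiety items consistent with the class band,
surgeon-rated cooperation VAS, heart rate at five intra-operative time
points, and treatment-break counts/durations, all monotone in class
severity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage

from .grid import REFERENCE_PX_PER_MM, TrackingGrid
from .ingest import MARK_RGB
from .metrics import (
    AnxietyClass,
    CLASS_ORDER,
    HADS_BORDERLINE_MAX,
    HADS_MAX_ITEM,
    HADS_N_ITEMS,
    HADS_NORMAL_MAX,
    PlotParameters,
    classify_hads,
)

HR_TIME_POINTS = ("baseline", "start", "flap", "ablation", "end")


@dataclass(frozen=True)
class ClassProfile:
    """Generating distribution for one anxiety class.

    ``bias_px`` is the mean dwell offset for a right eye, image coordinates
    (x positive rightward, y positive downward); negative x emulates the
    nasal shift and negative y the upward shift of real averaged plots.  The
    x component is mirrored for left eyes.

    The model is hierarchical: ``dispersion_px`` is the class *median* of
    the per-subject dwell scatter, and each subject's own dispersion is
    drawn lognormally around it (``dispersion_sigma_log`` on the log scale)
    with its own bias jittered by ``bias_sd_px``.  Without this
    between-subject level, every subject's parameters would collapse onto
    the class expectation and classes would separate unrealistically well;
    clinical cohorts show wide within-class interquartile ranges instead.

    Heart-rate means/SDs (beats/min) follow the five intra-operative time
    points with the ablation peak most pronounced in the case class.
    """

    dwell_count_range: tuple[int, int]
    dispersion_px: float
    bias_px: tuple[float, float]
    dispersion_sigma_log: float
    bias_sd_px: float
    vas_mean: float
    vas_sd: float
    hr_mean: tuple[float, float, float, float, float]
    hr_sd: tuple[float, float, float, float, float]
    break_rate: float
    break_duration_mean_s: float


#: Defaults per class.  Dwell counts are high enough that marks merge into a
#: few confluent islands (clinical plots show summed perimeters far below
#: what isolated marks would give), and dispersion/bias/count all rise with
#: severity, so cohort medians of (SA, SP, ACD) land near (630, 170, 11) /
#: (1100, 330, 20) / (2000, 630, 31) at the reference scale — the same order
#: of magnitude as the clinical cohort.  The wide dwell-count ranges carry
#: most of the between-subject area variability (decorrelating SA from SP
#: within class), the lognormal dispersion multiplier is kept tight, and the
#: bias jitter supplies independent centroid-deviation variability; VAS and
#: HR follow the clinical class-conditional means.
DEFAULT_PROFILES: dict[AnxietyClass, ClassProfile] = {
    AnxietyClass.NORMAL: ClassProfile(
        dwell_count_range=(49, 170),
        dispersion_px=5.5,
        bias_px=(-8.0, -6.0),
        dispersion_sigma_log=0.12,
        bias_sd_px=3.5,
        vas_mean=2.3,
        vas_sd=0.8,
        hr_mean=(65.5, 67.0, 66.1, 68.5, 68.0),
        hr_sd=(2.2, 2.3, 2.1, 2.0, 1.8),
        break_rate=0.2,
        break_duration_mean_s=2.0,
    ),
    AnxietyClass.BORDERLINE: ClassProfile(
        dwell_count_range=(69, 240),
        dispersion_px=8.0,
        bias_px=(-15.0, -11.0),
        dispersion_sigma_log=0.12,
        bias_sd_px=4.0,
        vas_mean=4.1,
        vas_sd=0.4,
        hr_mean=(65.4, 67.5, 67.3, 71.5, 70.0),
        hr_sd=(1.6, 3.1, 1.4, 3.5, 2.2),
        break_rate=0.3,
        break_duration_mean_s=2.5,
    ),
    AnxietyClass.CASE: ClassProfile(
        dwell_count_range=(101, 348),
        dispersion_px=11.5,
        bias_px=(-23.0, -18.0),
        dispersion_sigma_log=0.12,
        bias_sd_px=4.5,
        vas_mean=5.3,
        vas_sd=0.3,
        hr_mean=(69.8, 74.9, 75.5, 79.5, 79.9),
        hr_sd=(3.2, 5.0, 3.6, 6.2, 4.6),
        break_rate=0.7,
        break_duration_mean_s=4.0,
    ),
}

HADS_BANDS: dict[AnxietyClass, tuple[int, int]] = {
    AnxietyClass.NORMAL: (0, HADS_NORMAL_MAX),
    AnxietyClass.BORDERLINE: (HADS_NORMAL_MAX + 1, HADS_BORDERLINE_MAX),
    AnxietyClass.CASE: (HADS_BORDERLINE_MAX + 1, HADS_N_ITEMS * HADS_MAX_ITEM),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings."""

    n_per_class: int = 200
    mark_side_px: int = 5
    px_per_mm: float = REFERENCE_PX_PER_MM
    extent_mm: float = 3.0
    margin_px: int = 25
    seed: int = 0
    profiles: dict[AnxietyClass, ClassProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if self.mark_side_px < 1:
            raise ValueError("mark_side_px must be >= 1")
        disp = [self.profiles[c].dispersion_px for c in CLASS_ORDER]
        if not (disp[0] <= disp[1] <= disp[2]):
            raise ValueError(
                "class dispersions must be ordered normal <= borderline <= case"
            )
        half = int(round(self.extent_mm * self.px_per_mm))
        for cls in CLASS_ORDER:
            bx, by = self.profiles[cls].bias_px
            if max(abs(bx), abs(by)) + self.mark_side_px >= half:
                raise ValueError(
                    f"profile for {cls.value}: marks cannot fit inside the "
                    "tracking square"
                )

    def make_grid(self) -> TrackingGrid:
        half = int(round(self.extent_mm * self.px_per_mm))
        c = self.margin_px + half
        return TrackingGrid(
            center_px=(c, c), px_per_mm=self.px_per_mm, extent_mm=self.extent_mm
        )

    @property
    def image_size_px(self) -> int:
        half = int(round(self.extent_mm * self.px_per_mm))
        return 2 * (self.margin_px + half) + 1


@dataclass
class GroundTruth:
    """Everything known about one synthetic subject."""

    subject_id: str
    anxiety_class: AnxietyClass
    eye_side: str  # "right" | "left"
    square_origins: list[tuple[int, int]]  # (row, col) top-left corners
    mark_side_px: int
    grid: TrackingGrid
    hads_items: tuple[int, ...]
    vas: int
    heart_rate: dict[str, float]
    break_count: int
    break_duration_s: float

    @property
    def hads_sub_score(self) -> int:
        return sum(self.hads_items)

    @property
    def hads_class(self) -> AnxietyClass:
        return classify_hads(self.hads_sub_score)


def _sample_hads_items(rng: np.random.Generator, band: tuple[int, int]) -> tuple[int, ...]:
    """Uniform draw over 7-item vectors whose sum lies in the class band."""
    lo, hi = band
    while True:
        items = rng.integers(0, HADS_MAX_ITEM + 1, size=HADS_N_ITEMS)
        if lo <= int(items.sum()) <= hi:
            return tuple(int(i) for i in items)


def _sample_dwell_origins(
    rng: np.random.Generator,
    profile: ClassProfile,
    grid: TrackingGrid,
    side: int,
    mirror_x: bool,
) -> list[tuple[int, int]]:
    """Dwell squares as integer top-left corners, truncated to the grid."""
    count = int(rng.integers(profile.dwell_count_range[0], profile.dwell_count_range[1] + 1))
    # subject-specific dispersion (lognormal around the class median) and bias
    dispersion = profile.dispersion_px * float(np.exp(rng.normal(0.0, profile.dispersion_sigma_log)))
    bx, by = profile.bias_px
    if mirror_x:
        bx = -bx
    bx += float(rng.normal(0.0, profile.bias_sd_px))
    by += float(rng.normal(0.0, profile.bias_sd_px))
    r0, r1, c0, c1 = grid.bounds_px()
    cx, cy = grid.center_px
    origins: list[tuple[int, int]] = []
    while len(origins) < count:
        need = count - len(origins)
        dx = rng.normal(bx, dispersion, size=need)
        dy = rng.normal(by, dispersion, size=need)
        rows = np.round(cy + dy).astype(int) - side // 2
        cols = np.round(cx + dx).astype(int) - side // 2
        ok = (
            (rows >= r0)
            & (rows + side - 1 <= r1)
            & (cols >= c0)
            & (cols + side - 1 <= c1)
        )
        origins.extend(zip(rows[ok].tolist(), cols[ok].tolist()))
    return origins[:count]


def sample_cohort(config: SyntheticConfig) -> list[GroundTruth]:
    """Draw a full synthetic cohort; reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    grid = config.make_grid()
    cohort: list[GroundTruth] = []
    for cls in CLASS_ORDER:
        profile = config.profiles[cls]
        band = HADS_BANDS[cls]
        for i in range(config.n_per_class):
            eye = "right" if i % 2 == 0 else "left"
            origins = _sample_dwell_origins(
                rng, profile, grid, config.mark_side_px, mirror_x=(eye == "left")
            )
            items = _sample_hads_items(rng, band)
            vas = int(np.clip(round(rng.normal(profile.vas_mean, profile.vas_sd)), 1, 10))
            hr = {
                tp: float(rng.normal(m, s))
                for tp, m, s in zip(HR_TIME_POINTS, profile.hr_mean, profile.hr_sd)
            }
            n_breaks = int(rng.poisson(profile.break_rate))
            duration = (
                float(rng.gamma(2.0, profile.break_duration_mean_s / 2.0) * n_breaks)
                if n_breaks
                else 0.0
            )
            cohort.append(
                GroundTruth(
                    subject_id=f"{cls.value[:4]}-{i:04d}",
                    anxiety_class=cls,
                    eye_side=eye,
                    square_origins=origins,
                    mark_side_px=config.mark_side_px,
                    grid=grid,
                    hads_items=items,
                    vas=vas,
                    heart_rate=hr,
                    break_count=n_breaks,
                    break_duration_s=duration,
                )
            )
    return cohort


def _square_union_mask(truth: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    s = truth.mark_side_px
    for row, col in truth.square_origins:
        if row < 0 or col < 0 or row + s > shape[0] or col + s > shape[1]:
            raise ValueError(f"square at {(row, col)} falls outside the canvas")
        canvas[row : row + s, col : col + s] = True
    return canvas


def render_plot(truth: GroundTruth, image_size_px: int | None = None) -> np.ndarray:
    """Render a subject's plot as an RGB uint8 raster.

    White background, black tracking-square outline and crosshair, pure blue
    marks drawn last so mark pixels are exactly the analytic square union —
    rendering is the exact inverse of mark detection.
    """
    grid = truth.grid
    r0, r1, c0, c1 = grid.bounds_px()
    if image_size_px is None:
        image_size_px = r1 + min(r0, c0) + 1
    img = np.full((image_size_px, image_size_px, 3), 255, dtype=np.uint8)
    if r0 < 0 or c0 < 0 or r1 >= image_size_px or c1 >= image_size_px:
        raise ValueError("tracking square does not fit in the image")
    # tracking-square outline + crosshair (black: outside the mark color band)
    img[r0, c0 : c1 + 1] = 0
    img[r1, c0 : c1 + 1] = 0
    img[r0 : r1 + 1, c0] = 0
    img[r0 : r1 + 1, c1] = 0
    ccol = int(round(grid.center_px[0]))
    crow = int(round(grid.center_px[1]))
    img[crow, c0 : c1 + 1] = 0
    img[r0 : r1 + 1, ccol] = 0

    s = truth.mark_side_px
    for row, col in truth.square_origins:
        if not (grid.contains_px(row, col) and grid.contains_px(row + s - 1, col + s - 1)):
            raise ValueError(f"mark square at {(row, col)} lies outside the tracking grid")
        img[row : row + s, col : col + s] = MARK_RGB
    return img


def analytic_parameters(truth: GroundTruth) -> PlotParameters:
    """(SA, SP, ACD) by exact pixel enumeration of the square-union geometry.

    Serves as the independent oracle for the image pathway: the union mask
    is built directly from the ground-truth square coordinates, labeled with
    :func:`scipy.ndimage.label` (8-connectivity) and measured without any
    rendering or color detection.
    """
    r1 = truth.grid.bounds_px()[1]
    c1 = truth.grid.bounds_px()[3]
    shape = (r1 + 2, c1 + 2)
    canvas = _square_union_mask(truth, shape)
    if not canvas.any():
        return PlotParameters(sa=0.0, sp=0.0, acd=0.0)
    labels, n = ndimage.label(canvas, structure=np.ones((3, 3), dtype=bool))
    slices = ndimage.find_objects(labels)
    cx, cy = truth.grid.center_px
    areas: list[float] = []
    perims: list[float] = []
    dists: list[float] = []
    for k, (row_sl, col_sl) in enumerate(slices, start=1):
        blob = labels[row_sl, col_sl] == k
        # boundary edges: foreground pixels whose 4-neighbour is background
        p = 0
        for shift_axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            neighbour = np.roll(blob, shift, axis=shift_axis)
            idx = [slice(None)] * 2
            idx[shift_axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            neighbour[tuple(idx)] = False
            p += int(np.count_nonzero(blob & ~neighbour))
        rows, cols = np.nonzero(blob)
        crow = rows.mean() + row_sl.start
        ccol = cols.mean() + col_sl.start
        areas.append(float(rows.size))
        perims.append(float(p))
        dists.append(float(np.hypot(ccol - cx, crow - cy)))
    sa = float(canvas.sum())
    sp = math.fsum(perims)
    acd = math.fsum(a * d for a, d in zip(areas, dists)) / math.fsum(areas)
    return PlotParameters(sa=sa, sp=sp, acd=acd)


def cohort_metadata_frame(cohort: list[GroundTruth]) -> pd.DataFrame:
    """Per-subject metadata table (HADS items, VAS, HR, breaks)."""
    rows = []
    for t in cohort:
        row = {
            "subject_id": t.subject_id,
            "anxiety_class": t.anxiety_class.value,
            "eye_side": t.eye_side,
            "vas": t.vas,
            "break_count": t.break_count,
            "break_duration_s": t.break_duration_s,
            "hads_sub_score": t.hads_sub_score,
            "hads_class": t.hads_class.value,
        }
        row.update({f"hads_item_{j + 1}": v for j, v in enumerate(t.hads_items)})
        row.update({f"hr_{tp}": t.heart_rate[tp] for tp in HR_TIME_POINTS})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_parameters_frame(cohort: list[GroundTruth]) -> pd.DataFrame:
    """Analytic (SA, SP, ACD) per subject, from the ground-truth geometry."""
    rows = []
    for t in cohort:
        p = analytic_parameters(t)
        rows.append(
            {
                "subject_id": t.subject_id,
                "anxiety_class": t.anxiety_class.value,
                "sa": p.sa,
                "sp": p.sp,
                "acd": p.acd,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    cohort: list[GroundTruth],
    config: SyntheticConfig,
    out_dir: str | Path,
    write_images: bool = True,
) -> dict[str, Path]:
    """Write plots, ground truth, metadata and config; returns artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if write_images:
        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        sidecar_rows = []
        for t in cohort:
            img = render_plot(t, config.image_size_px)
            path = plot_dir / f"{t.subject_id}.png"
            Image.fromarray(img).save(path, format="PNG")
            sidecar_rows.append(
                {
                    "image": path.name,
                    "center_x_px": t.grid.center_px[0],
                    "center_y_px": t.grid.center_px[1],
                    "px_per_mm": t.grid.px_per_mm,
                    "eye_side": t.eye_side,
                    "subject_id": t.subject_id,
                }
            )
        sidecar = out / "plots_sidecar.csv"
        pd.DataFrame(
            sidecar_rows,
            columns=[
                "image",
                "center_x_px",
                "center_y_px",
                "px_per_mm",
                "eye_side",
                "subject_id",
            ],
        ).to_csv(sidecar, index=False)
        artifacts["plots"] = plot_dir
        artifacts["sidecar"] = sidecar

    squares = pd.DataFrame(
        [
            {"subject_id": t.subject_id, "row": r, "col": c, "side_px": t.mark_side_px}
            for t in cohort
            for r, c in t.square_origins
        ]
    )
    artifacts["squares"] = out / "ground_truth_squares.csv"
    squares.to_csv(artifacts["squares"], index=False)

    artifacts["parameters"] = out / "ground_truth_parameters.csv"
    cohort_parameters_frame(cohort).to_csv(artifacts["parameters"], index=False)

    artifacts["metadata"] = out / "metadata.csv"
    cohort_metadata_frame(cohort).to_csv(artifacts["metadata"], index=False)

    artifacts["config"] = out / "synthetic_config.yaml"
    cfg = {
        "n_per_class": config.n_per_class,
        "mark_side_px": config.mark_side_px,
        "px_per_mm": config.px_per_mm,
        "extent_mm": config.extent_mm,
        "margin_px": config.margin_px,
        "seed": config.seed,
        "profiles": {
            cls.value: {
                "dwell_count_range": list(p.dwell_count_range),
                "dispersion_px": p.dispersion_px,
                "bias_px": list(p.bias_px),
                "dispersion_sigma_log": p.dispersion_sigma_log,
                "bias_sd_px": p.bias_sd_px,
                "vas_mean": p.vas_mean,
                "vas_sd": p.vas_sd,
                "hr_mean": list(p.hr_mean),
                "hr_sd": list(p.hr_sd),
                "break_rate": p.break_rate,
                "break_duration_mean_s": p.break_duration_mean_s,
            }
            for cls, p in config.profiles.items()
        },
    }
    with open(artifacts["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return artifacts
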