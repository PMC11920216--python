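"""Fixation-instability metrics: SA, SP, ACD, FIS and HADS anxiety scoring.

Three morphometric parameters summarize a pupil-center plot:

* **SA** (sum area) — total number of mark pixels (union of the possibly
  overlapping mark squares).
* **SP** (sum perimeter) — summed boundary-edge perimeter of the connected
  mark clusters.
* **ACD** (average centroid deviation) — area-weighted mean Euclidean
  distance of cluster centroids from the tracking-area center; large
  clusters pull the average harder than small ones.

The fixation instability score (FIS) is a fixed linear combination of the
three, calibrated against the seven-item HADS anxiety sub-score:

    FIS = 0.005 * SA + 0.027 * SP + 0.213 * ACD + 4.458

On the 0-90 scale, FIS <= 12 reads as normal, 13-36 as borderline anxiety
and 37-90 as an anxiety case; the real-valued boundaries are <= 12 and
<= 36 (consistent with the integer bands).  The coefficients live in a
:class:`FISCoefficients` config object so the score can be recalibrated for
a different device without code change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .ingest import ClusterSet


class AnxietyClass(str, Enum):
    NORMAL = "normal"
    BORDERLINE = "borderline"
    CASE = "case"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Severity order used for monotonicity checks and ROC positive classes.
CLASS_ORDER: tuple[AnxietyClass, ...] = (
    AnxietyClass.NORMAL,
    AnxietyClass.BORDERLINE,
    AnxietyClass.CASE,
)


@dataclass(frozen=True)
class FISCoefficients:
    """Linear-model coefficients of the fixation instability score."""

    sa: float = 0.005
    sp: float = 0.027
    acd: float = 0.213
    intercept: float = 4.458


DEFAULT_FIS_COEFFICIENTS = FISCoefficients()

#: Real-valued class boundaries on the FIS scale: normal <= 12 < borderline
#: <= 36 < case (equivalent to the integer bands 0-12 / 13-36 / 37-90).
FIS_NORMAL_MAX = 12.0
FIS_BORDERLINE_MAX = 36.0
FIS_SCALE_MAX = 90

#: HADS anxiety sub-score bands: normal <= 7, borderline 8-10, case 11-21.
HADS_NORMAL_MAX = 7
HADS_BORDERLINE_MAX = 10
HADS_N_ITEMS = 7
HADS_MAX_ITEM = 3


@dataclass(frozen=True)
class PlotParameters:
    """The (SA, SP, ACD) triple for one plot, in reference-pixel units."""

    sa: float
    sp: float
    acd: float

    def __post_init__(self) -> None:
        # For measured plots SA = 0, SP = 0 and emptiness coincide (guaranteed
        # by compute_parameters); direct construction allows free triples so
        # the linear model can be probed coordinate-wise.
        if self.sa < 0 or self.sp < 0 or self.acd < 0:
            raise ValueError("SA, SP and ACD must be non-negative")

    @property
    def is_empty(self) -> bool:
        return self.sa == 0


@dataclass(frozen=True)
class FISResult:
    fis_raw: float
    fis_scale: int
    anxiety_class: AnxietyClass


@dataclass(frozen=True)
class HADSResponse:
    items: tuple[int, ...]
    sub_score: int
    hads_class: AnxietyClass


def compute_parameters(cluster_set: ClusterSet) -> PlotParameters:
    """Measure SA, SP and ACD from a set of connected mark clusters.

    SA is the union pixel area, SP the sum of cluster perimeters and ACD the
    area-weighted mean centroid distance to the grid center.  An empty
    cluster set (a perfectly stable plot) yields (0, 0, 0) by convention.
    """
    if len(cluster_set) == 0:
        return PlotParameters(sa=0.0, sp=0.0, acd=0.0)
    sa = float(cluster_set.union_area)
    # fsum: exact, order-independent accumulation, so the result does not
    # depend on the labeling order of the clusters
    sp = math.fsum(c.perimeter for c in cluster_set.clusters)
    total_area = math.fsum(float(c.pixel_area) for c in cluster_set.clusters)
    weighted = math.fsum(
        c.pixel_area * c.distance_to_center for c in cluster_set.clusters
    )
    return PlotParameters(sa=sa, sp=sp, acd=weighted / total_area)


def compute_fis(
    params: PlotParameters,
    coefficients: FISCoefficients = DEFAULT_FIS_COEFFICIENTS,
) -> FISResult:
    """Evaluate the FIS linear model and place the result on the 0-90 scale.

    The integer scale value rounds half up and clips to [0, 90]; the anxiety
    class follows the real-valued boundaries (<= 12 normal, <= 36
    borderline, above that case).
    """
    fis_raw = (
        coefficients.sa * params.sa
        + coefficients.sp * params.sp
        + coefficients.acd * params.acd
        + coefficients.intercept
    )
    fis_scale = int(min(max(math.floor(fis_raw + 0.5), 0), FIS_SCALE_MAX))
    return FISResult(
        fis_raw=fis_raw, fis_scale=fis_scale, anxiety_class=classify_fis(fis_raw)
    )


def classify_fis(fis_raw: float) -> AnxietyClass:
    """Assign the anxiety class for a raw FIS value."""
    if not math.isfinite(fis_raw):
        raise ValueError(f"FIS must be finite, got {fis_raw!r}")
    if fis_raw <= FIS_NORMAL_MAX:
        return AnxietyClass.NORMAL
    if fis_raw <= FIS_BORDERLINE_MAX:
        return AnxietyClass.BORDERLINE
    return AnxietyClass.CASE


def classify_hads(sub_score: int) -> AnxietyClass:
    """Band a HADS anxiety sub-score: <=7 normal, 8-10 borderline, 11-21 case."""
    if not 0 <= sub_score <= HADS_N_ITEMS * HADS_MAX_ITEM:
        raise ValueError(f"HADS sub-score must be in [0, 21], got {sub_score}")
    if sub_score <= HADS_NORMAL_MAX:
        return AnxietyClass.NORMAL
    if sub_score <= HADS_BORDERLINE_MAX:
        return AnxietyClass.BORDERLINE
    return AnxietyClass.CASE


def score_hads(items) -> HADSResponse:
    """Score the seven-item HADS anxiety instrument.

    Each item is the response level 0-3 ("only occasionally" = 0 up to
    "a great deal of time" = 3); the sub-score is their sum (0-21).
    """
    items = tuple(int(i) for i in items)
    if len(items) != HADS_N_ITEMS:
        raise ValueError(f"expected {HADS_N_ITEMS} HADS items, got {len(items)}")
    if any(i < 0 or i > HADS_MAX_ITEM for i in items):
        raise ValueError(f"HADS items must be in 0..{HADS_MAX_ITEM}: {items}")
    sub_score = sum(items)
    return HADSResponse(items=items, sub_score=sub_score, hads_class=classify_hads(sub_score))
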