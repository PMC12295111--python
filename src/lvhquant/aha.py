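"""AHA angular partitioning of the left ventricle.

The standard AHA model divides the LV into 17 segments: six 60-degree
segments at the basal level, six at the mid-cavity level, four 90-degree
segments at the apical level, and a single apex region. The refined model
used throughout this package splits every non-apex segment into three equal
angular sub-segments (20 degrees basal/mid, 30 degrees apical), giving
18 + 18 + 12 + 1 = 49 regions.

Angles are measured in degrees, counterclockwise as displayed (image
origin top-left, row axis pointing down), with 0 degrees on the ray from
the LV cavity center through the anterior RV insertion point. Partition
bins are stored relative to that anchor and are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

LEVELS = ("basal", "mid", "apical")
APEX = "apex"

#: angular span of one AHA segment per level, degrees
SEGMENT_SPAN = {"basal": 60.0, "mid": 60.0, "apical": 90.0}
#: AHA segment ids per level
SEGMENT_IDS = {"basal": (1, 2, 3, 4, 5, 6), "mid": (7, 8, 9, 10, 11, 12), "apical": (13, 14, 15, 16)}
APEX_SEGMENT_ID = 17


def direction(angle_deg: float) -> tuple[float, float]:
    """Unit vector (drow, dcol) for an angle, CCW as displayed."""
    a = math.radians(angle_deg)
    return (-math.sin(a), math.cos(a))


def angle_of(point: Sequence[float], center: Sequence[float]) -> float:
    """Angle in [0, 360) of ``point`` seen from ``center`` (pixel coords)."""
    drow = point[0] - center[0]
    dcol = point[1] - center[1]
    return math.degrees(math.atan2(-drow, dcol)) % 360.0


@dataclass(frozen=True)
class LandmarkSet:
    """LV cavity center plus the two LV-RV insertion angles (degrees)."""

    lv_center: tuple[float, float]
    anterior_rv_insertion: float
    inferior_rv_insertion: float

    def __post_init__(self) -> None:
        if math.isclose((self.anterior_rv_insertion - self.inferior_rv_insertion) % 360.0, 0.0):
            raise ValueError("RV insertion angles must be distinct modulo 360")


@dataclass(frozen=True)
class RegionBin:
    region_id: int
    segment_id: int
    sub_index: int | None  # 1-3 within the parent segment; None for apex / 17-mode
    level: str
    start_deg: float  # relative to the anterior-insertion anchor, in [0, 360)
    end_deg: float


@dataclass
class RegionPartition:
    """Angular bins per slice level, anchored at the anterior RV insertion."""

    mode: int
    bins: list[RegionBin]
    anchor_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in (17, 49):
            raise ValueError(f"partition mode must be 17 or 49, got {self.mode}")

    @property
    def region_ids(self) -> list[int]:
        return [b.region_id for b in self.bins]

    def bins_for(self, level: str) -> list[RegionBin]:
        return [b for b in self.bins if b.level == level]

    def bin_by_id(self, region_id: int) -> RegionBin:
        for b in self.bins:
            if b.region_id == region_id:
                return b
        raise KeyError(f"no region {region_id} in partition")

    def absolute_span(self, region_id: int) -> tuple[float, float]:
        """Bin boundaries in absolute image angles (degrees)."""
        b = self.bin_by_id(region_id)
        return ((b.start_deg + self.anchor_deg) % 360.0, (b.end_deg - b.start_deg))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "region_id": b.region_id,
                    "segment_id": b.segment_id,
                    "sub_index": b.sub_index,
                    "level": b.level,
                    "start_deg": b.start_deg,
                    "end_deg": b.end_deg,
                }
                for b in self.bins
            ]
        )


def build_partition(landmarks: LandmarkSet, levels: Iterable[str], mode: int = 49) -> RegionPartition:
    """Partition the supplied slice levels into AHA (sub-)segments.

    Segment boundaries are anchored so that relative angle 0 lies on the ray
    through the anterior RV insertion. AHA numbering: basal 1-6, mid 7-12,
    apical 13-16, apex 17. In 49-mode every non-apex segment is split into
    three equal sub-bins ordered by increasing angle; the apex is never
    subdivided. Region ids are canonical: basal sub-bins 1-18, mid 19-36,
    apical 37-48, apex 49 (in 17-mode the region id is the segment id).
    """
    if mode not in (17, 49):
        raise ValueError(f"partition mode must be 17 or 49, got {mode}")
    levels = list(levels)
    bins: list[RegionBin] = []
    region_counter = 0
    for level in LEVELS:
        if level not in levels:
            continue
        span = SEGMENT_SPAN[level]
        n_sub = 3 if mode == 49 else 1
        sub_span = span / n_sub
        offset = {"basal": 0, "mid": 18, "apical": 36}[level] if mode == 49 else 0
        for i, seg_id in enumerate(SEGMENT_IDS[level]):
            for s in range(n_sub):
                start = i * span + s * sub_span
                if mode == 49:
                    region_id = offset + i * n_sub + s + 1
                    sub_index: int | None = s + 1
                else:
                    region_id = seg_id
                    sub_index = None
                bins.append(
                    RegionBin(region_id, seg_id, sub_index, level, start, start + sub_span)
                )
                region_counter += 1
    if APEX in levels:
        apex_id = 49 if mode == 49 else APEX_SEGMENT_ID
        bins.append(RegionBin(apex_id, APEX_SEGMENT_ID, None, APEX, 0.0, 360.0))
    return RegionPartition(mode=mode, bins=bins, anchor_deg=landmarks.anterior_rv_insertion % 360.0)


def region_of(angle_deg: float, level: str, partition: RegionPartition) -> int:
    """Region id containing an absolute image angle at the given level."""
    if level == APEX:
        apex_bins = partition.bins_for(APEX)
        if not apex_bins:
            raise KeyError("partition has no apex region")
        return apex_bins[0].region_id
    rel = (angle_deg - partition.anchor_deg) % 360.0
    for b in partition.bins_for(level):
        if b.start_deg <= rel < b.end_deg:
            return b.region_id
    raise KeyError(f"no bin covers angle {angle_deg} at level {level!r}")


def detect_landmarks(
    mask: np.ndarray,
    override: LandmarkSet | None = None,
    rv_mask: np.ndarray | None = None,
    insertion_angles: tuple[float, float] | None = None,
) -> LandmarkSet:
    """Locate the LV cavity center and the RV insertion angles.

    The center is the centroid of the cavity, i.e. the hole enclosed by the
    myocardium mask. Insertion angles come from ``override`` (returned
    verbatim), an explicit ``insertion_angles`` pair, or a contact-arc
    heuristic when an RV label mask is provided: the angles of RV pixels
    touching the epicardium are clustered into one arc and its two endpoints
    are reported (the counterclockwise endpoint as the anterior insertion).
    """
    if override is not None:
        return override
    mask = np.asarray(mask).astype(bool)
    filled = ndimage.binary_fill_holes(mask)
    cavity = filled & ~mask
    if not cavity.any():
        raise ValueError("no LV cavity found in mask and no landmark override given")
    center = ndimage.center_of_mass(cavity)
    if insertion_angles is not None:
        ant, inf = insertion_angles
    elif rv_mask is not None:
        ant, inf = _rv_contact_angles(mask, np.asarray(rv_mask).astype(bool), center)
    else:
        raise ValueError("RV insertion angles unavailable: supply override, "
                         "insertion_angles, or an RV mask")
    return LandmarkSet(lv_center=(float(center[0]), float(center[1])),
                       anterior_rv_insertion=float(ant) % 360.0,
                       inferior_rv_insertion=float(inf) % 360.0)


def _rv_contact_angles(lv_mask: np.ndarray, rv_mask: np.ndarray, center) -> tuple[float, float]:
    contact = ndimage.binary_dilation(lv_mask, iterations=2) & rv_mask
    if not contact.any():
        raise ValueError("RV mask does not touch the LV epicardium")
    rows, cols = np.nonzero(contact)
    angles = np.sort(np.degrees(np.arctan2(-(rows - center[0]), cols - center[1])) % 360.0)
    # the contact arc is the complement of the largest angular gap
    gaps = np.diff(np.concatenate([angles, angles[:1] + 360.0]))
    k = int(np.argmax(gaps))
    arc_start = angles[(k + 1) % len(angles)]  # CW end of the arc
    arc_end = angles[k]  # CCW end of the arc
    return float(arc_end), float(arc_start)


def assign_slice_levels(
    stack_or_n,
    has_cavity: Sequence[bool] | None = None,
    explicit: Sequence[str] | None = None,
) -> list[str]:
    """Label slices (ordered base to apex) as basal / mid / apical / apex.

    Explicit labels pass through unchanged. Otherwise every trailing slice
    without a cavity is the apex and the remaining slices are split into
    three contiguous thirds from base to apex, ties going to the more basal
    level (10 slices -> 4/3/3).
    """
    if explicit is not None:
        return list(explicit)
    if hasattr(stack_or_n, "slices"):
        labels = getattr(stack_or_n, "level_labels", None)
        if labels is not None:
            return list(labels)
        n = len(stack_or_n.slices)
    else:
        n = int(stack_or_n)
    if has_cavity is None:
        has_cavity = [True] * n
    has_cavity = list(has_cavity)
    if len(has_cavity) != n:
        raise ValueError("has_cavity length must match slice count")
    n_apex = 0
    while n_apex < n and not has_cavity[n - 1 - n_apex]:
        n_apex += 1
    n_ring = n - n_apex
    if n_ring < 3:
        raise ValueError("need at least 3 cavity-bearing slices to assign levels")
    q, r = divmod(n_ring, 3)
    counts = [q + (1 if r >= 1 else 0), q + (1 if r >= 2 else 0), q]
    labels = ["basal"] * counts[0] + ["mid"] * counts[1] + ["apical"] * counts[2]
    labels += [APEX] * n_apex
    return labels
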