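"""Synthetic short-axis phantoms with analytic ground truth.

Each phantom slice is an annular myocardium around a circular cavity: the
endocardium is a circle of ``cavity_radius`` and the epicardium at image
angle ``a`` lies ``thickness_profile(a)`` millimetres beyond it, so the
per-angle wall thickness is known in closed form and every downstream stage
(partitioning, thickness measurement, scoring, classification) can be
tested against exact truth. The apex slice is a filled disc, reflecting the
absence of a cavity at the apex. Intensities mimic balanced-SSFP cine
contrast (bright blood pool, mid-gray myocardium, dark background) with
additive Gaussian noise clipped to [0, 1]; no attempt is made at MR physics
(coil shading, banding, papillary muscles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from lvhquant.aha import APEX, LEVELS, LandmarkSet, RegionPartition, build_partition
from lvhquant.contours import ContourSet, SliceContours, circle_polygon
from lvhquant.imaging_io import ShortAxisStack
from lvhquant.severity import score_severity

Profile = Callable[[np.ndarray], np.ndarray]

#: severity bands used when drawing per-region target thicknesses (mm)
SEVERITY_BANDS = {0: (6.0, 14.5), 1: (15.0, 20.0), 2: (20.1, 25.0), 3: (25.1, 32.0)}


def constant_profile(mm: float) -> Profile:
    def f(a):
        return np.full_like(np.asarray(a, dtype=float), float(mm))

    return f


def piecewise_profile(breaks_deg: Sequence[float], values_mm: Sequence[float]) -> Profile:
    """Piecewise-constant thickness over half-open angular intervals.

    ``breaks_deg`` are the interval start angles (absolute image degrees,
    ascending within [0, 360)); interval ``i`` spans ``[breaks[i],
    breaks[i+1])`` with wraparound for the last one.
    """
    breaks = np.asarray(breaks_deg, dtype=float)
    values = np.asarray(values_mm, dtype=float)
    if len(breaks) != len(values):
        raise ValueError("breaks and values must have equal length")

    def f(a):
        a = np.asarray(a, dtype=float) % 360.0
        idx = np.searchsorted(breaks, a, side="right") - 1
        idx = np.where(idx < 0, len(breaks) - 1, idx)
        return values[idx]

    return f


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise parameters of one synthetic subject.

    ``thickness_profile`` may be a single callable applied to every ring
    level or a mapping ``{level: callable}`` for basal/mid/apical. Defaults
    describe a normal ventricle: 25 mm cavity radius, uniform 10 mm wall,
    1.25 mm isotropic pixels on a 256-pixel grid (320 mm field of view).
    """

    image_size: int = 256
    pixel_spacing: float = 1.25
    n_slices_per_level: int = 3
    cavity_radius: float = 25.0
    thickness_profile: Profile | Mapping[str, Profile] | float = 10.0
    apex_radius: float = 6.0
    rv_insertion_angles: tuple[float, float] = (30.0, 150.0)
    myocardium_intensity: float = 0.45
    cavity_intensity: float = 0.9
    background_intensity: float = 0.05
    noise_sd: float = 0.03
    seed: int = 0
    subject_id: str = "phantom"

    def profile_for(self, level: str) -> Profile:
        p = self.thickness_profile
        if isinstance(p, Mapping):
            p = p[level]
        if isinstance(p, (int, float)):
            return constant_profile(float(p))
        return p

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if self.n_slices_per_level < 1:
            raise ValueError("n_slices_per_level must be >= 1")
        probe = np.arange(0.0, 360.0, 0.25)
        max_t = 0.0
        for level in LEVELS:
            t = np.asarray(self.profile_for(level)(probe), dtype=float)
            if np.any(t <= 0):
                raise ValueError("thickness_profile must be positive on [0, 360)")
            max_t = max(max_t, float(t.max()))
        outer_mm = self.cavity_radius + max_t
        half_field_mm = (self.image_size / 2 - 2) * self.pixel_spacing
        if outer_mm > half_field_mm:
            raise ValueError(
                f"geometry overflow: annulus radius {outer_mm:.1f} mm exceeds the "
                f"usable half field of view {half_field_mm:.1f} mm"
            )
        if self.apex_radius <= 0 or self.apex_radius > half_field_mm:
            raise ValueError("apex_radius outside the usable field of view")


@dataclass
class PhantomTruth:
    """Exact contours, landmarks, per-region thickness and severity."""

    contours: ContourSet
    landmarks: LandmarkSet
    partition: RegionPartition
    rwt_truth: dict[int, float]
    severity_truth: dict[int, int]
    masks: list[np.ndarray] = field(default_factory=list)


def generate_phantom(spec: PhantomSpec) -> tuple[ShortAxisStack, PhantomTruth]:
    """Render one phantom stack and its analytic ground truth.

    Slices are ordered base to apex: ``n_slices_per_level`` each of basal,
    mid and apical rings, then one apex disc. Truth contours are the exact
    analytic polygons sampled at 1-degree resolution; truth thickness per
    region is the profile mean over the region's angular bin.
    """
    spec.validate()
    n = spec.image_size
    center = (n / 2.0, n / 2.0)
    sp = spec.pixel_spacing
    rng = np.random.default_rng(spec.seed)

    rows = np.arange(n)[:, None] - center[0]
    cols = np.arange(n)[None, :] - center[1]
    radius_mm = np.hypot(rows, cols) * sp
    angle_deg = np.degrees(np.arctan2(-rows, np.broadcast_to(cols, (n, n)))) % 360.0

    landmarks = LandmarkSet(
        lv_center=center,
        anterior_rv_insertion=spec.rv_insertion_angles[0],
        inferior_rv_insertion=spec.rv_insertion_angles[1],
    )
    partition = build_partition(landmarks, list(LEVELS) + [APEX], mode=49)

    slices: list[np.ndarray] = []
    labels: list[str] = []
    contour_slices: list[SliceContours] = []
    masks: list[np.ndarray] = []
    for level in LEVELS:
        profile = spec.profile_for(level)
        t_grid = np.asarray(profile(angle_deg), dtype=float)
        myo = (radius_mm >= spec.cavity_radius) & (radius_mm <= spec.cavity_radius + t_grid)
        # partial-volume rendering: boundaries blend over one pixel width,
        # as in-plane partial-volume averaging does in cine MR
        w = sp
        f_cav = np.clip((spec.cavity_radius - radius_mm) / w + 0.5, 0.0, 1.0)
        f_wall = np.clip((radius_mm - spec.cavity_radius) / w + 0.5, 0.0, 1.0) * np.clip(
            (spec.cavity_radius + t_grid - radius_mm) / w + 0.5, 0.0, 1.0
        )
        clean = (
            spec.cavity_intensity * f_cav
            + spec.myocardium_intensity * f_wall
            + spec.background_intensity * np.clip(1.0 - f_cav - f_wall, 0.0, 1.0)
        )
        ang = np.arange(0.0, 360.0, 1.0)
        endo = circle_polygon(center, spec.cavity_radius / sp)
        t_line = np.asarray(profile(ang), dtype=float)
        r_epi = (spec.cavity_radius + t_line) / sp
        epi = np.column_stack(
            [center[0] - r_epi * np.sin(np.deg2rad(ang)), center[1] + r_epi * np.cos(np.deg2rad(ang))]
        )
        for _ in range(spec.n_slices_per_level):
            slices.append(_with_noise(clean, rng, spec.noise_sd))
            labels.append(level)
            contour_slices.append(SliceContours(epi=epi.copy(), endo=endo.copy(), level=level))
            masks.append(myo.copy())

    # apex: filled disc, epicardial contour only
    apex_myo = radius_mm <= spec.apex_radius
    f_apex = np.clip((spec.apex_radius - radius_mm) / sp + 0.5, 0.0, 1.0)
    apex_clean = spec.myocardium_intensity * f_apex + spec.background_intensity * (1.0 - f_apex)
    slices.append(_with_noise(apex_clean, rng, spec.noise_sd))
    labels.append(APEX)
    contour_slices.append(
        SliceContours(epi=circle_polygon(center, spec.apex_radius / sp), endo=None, level=APEX)
    )
    masks.append(apex_myo)

    rwt = truth_rwt(spec, partition)
    severity = {rid: int(score_severity(v)) for rid, v in rwt.items()}
    stack = ShortAxisStack(slices, (sp, sp), labels, spec.subject_id)
    truth = PhantomTruth(
        contours=ContourSet(contour_slices, (sp, sp)),
        landmarks=landmarks,
        partition=partition,
        rwt_truth=rwt,
        severity_truth=severity,
        masks=masks,
    )
    return stack, truth


def truth_rwt(spec: PhantomSpec, partition: RegionPartition, step: float = 0.05) -> dict[int, float]:
    """Analytic per-region mean thickness: profile mean over each bin."""
    out: dict[int, float] = {}
    for b in partition.bins:
        if b.level == APEX:
            out[b.region_id] = 2.0 * spec.apex_radius
            continue
        start_abs = (b.start_deg + partition.anchor_deg) % 360.0
        ang = start_abs + np.arange(0.0, b.end_deg - b.start_deg, step)
        t = np.asarray(spec.profile_for(b.level)(ang), dtype=float)
        out[b.region_id] = float(t.mean())
    return out


def _with_noise(clean: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    if sd == 0:
        return clean.astype(float)
    return np.clip(clean + rng.normal(0.0, sd, size=clean.shape), 0.0, 1.0)


def make_cohort(
    n_patients: int,
    severity_mix: Sequence[float] = (0.55, 0.20, 0.15, 0.10),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[ShortAxisStack, PhantomTruth]]:
    """Generate a cohort of phantoms with region scores drawn from a mix.

    For every one of the 49 regions of every patient a severity class is
    drawn from ``severity_mix`` and a target thickness is sampled uniformly
    within that class's band (normal 6-14.5 mm, mild 15-20, moderate
    20.1-25, severe 25.1-32); the slice-level profiles are the resulting
    piecewise-constant functions over the partition bins, so the ground
    truth scores realize the requested mix. The default mix reflects an
    LVH-enriched clinical case load in which most regions remain normal.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    mix = np.asarray(severity_mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("severity_mix must be 4 non-negative proportions summing to 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    landmarks = LandmarkSet((0.0, 0.0), base.rv_insertion_angles[0], base.rv_insertion_angles[1])
    partition = build_partition(landmarks, list(LEVELS) + [APEX], mode=49)

    cohort = []
    for p in range(n_patients):
        profiles: dict[str, Profile] = {}
        apex_radius = base.apex_radius
        for level in LEVELS:
            bins = partition.bins_for(level)
            classes = rng.choice(4, size=len(bins), p=mix)
            values = np.array(
                [rng.uniform(*SEVERITY_BANDS[int(c)]) for c in classes]
            )
            breaks = [(b.start_deg + partition.anchor_deg) % 360.0 for b in bins]
            order = np.argsort(breaks)
            profiles[level] = piecewise_profile(
                np.asarray(breaks)[order], values[order]
            )
        apex_class = int(rng.choice(4, p=mix))
        apex_radius = rng.uniform(*SEVERITY_BANDS[apex_class]) / 2.0
        spec = replace(
            base,
            thickness_profile=profiles,
            apex_radius=apex_radius,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=f"{base.subject_id}-{p:03d}",
        )
        cohort.append(generate_phantom(spec))
    return cohort
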