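"""Endo/epicardial contour containers and JSON serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass
class SliceContours:
    """Closed, ordered polygons for one slice, in (row, col) pixel coords.

    ``endo`` is ``None`` on apex slices, where the LV appears as a filled
    disc without a cavity.
    """

    epi: np.ndarray
    endo: np.ndarray | None
    level: str

    def __post_init__(self) -> None:
        self.epi = np.asarray(self.epi, dtype=float)
        if self.endo is not None:
            self.endo = np.asarray(self.endo, dtype=float)
        if self.epi.ndim != 2 or self.epi.shape[1] != 2 or len(self.epi) < 3:
            raise ValueError("epi contour must be an (N>=3, 2) vertex array")
        if self.endo is not None and (self.endo.ndim != 2 or self.endo.shape[1] != 2):
            raise ValueError("endo contour must be an (N, 2) vertex array")


@dataclass
class ContourSet:
    """Per-slice contours plus the pixel spacing they are drawn in."""

    slices: list[SliceContours]
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))

    def __len__(self) -> int:
        return len(self.slices)

    def for_level(self, level: str) -> list[SliceContours]:
        return [s for s in self.slices if s.level == level]

    def to_json(self, path: str) -> str:
        payload = {
            "spacing": list(self.spacing),
            "slices": [
                {
                    "level": s.level,
                    "epi": s.epi.tolist(),
                    "endo": None if s.endo is None else s.endo.tolist(),
                }
                for s in self.slices
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path: str) -> "ContourSet":
        with open(path) as fh:
            payload = json.load(fh)
        slices = [
            SliceContours(
                epi=np.asarray(s["epi"], dtype=float),
                endo=None if s["endo"] is None else np.asarray(s["endo"], dtype=float),
                level=s["level"],
            )
            for s in payload["slices"]
        ]
        return cls(slices=slices, spacing=tuple(payload["spacing"]))


def circle_polygon(center, radius_px: float, step_deg: float = 1.0) -> np.ndarray:
    """Closed circle sampled every ``step_deg`` degrees, (row, col) vertices."""
    ang = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    rows = center[0] - radius_px * np.sin(ang)
    cols = center[1] + radius_px * np.cos(ang)
    return np.column_stack([rows, cols])
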