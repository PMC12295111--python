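"""Bull's-eye diagrams of per-region severity.

The polar layout mirrors the angular partition: basal regions on the
outer ring, mid-cavity in the middle, apical on the inner ring and the
apex as the central disc. Wedge spans equal the partition bin spans (20
degrees on the outer two rings and 30 degrees on the inner ring in
49-mode; 60/60/90 in 17-mode). Scores are drawn with four discrete
colors (the palette is configurable); output is SVG or PNG by file
extension with deterministic geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Circle, Wedge

from lvhquant.aha import APEX, RegionPartition
from lvhquant.severity import CLASS_NAMES, SeverityMap

#: score -> fill color (normal, mild, moderate, severe)
DEFAULT_COLORS = {0: "#2ca25f", 1: "#ffd92f", 2: "#fc8d59", 3: "#d7301f"}

RING_RADII = {"basal": (0.75, 1.0), "mid": (0.5, 0.75), "apical": (0.25, 0.5), APEX: (0.0, 0.25)}


@dataclass(frozen=True)
class RegionPatch:
    region_id: int
    level: str
    start_deg: float  # absolute display angle
    end_deg: float
    inner_frac: float
    outer_frac: float

    @property
    def centroid(self) -> tuple[float, float]:
        if self.level == APEX:
            return (0.0, 0.0)
        mid = np.deg2rad((self.start_deg + self.end_deg) / 2.0)
        r = (self.inner_frac + self.outer_frac) / 2.0
        return (r * np.cos(mid), r * np.sin(mid))


@dataclass
class BullseyeLayout:
    mode: int
    patches: list[RegionPatch]
    colors: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def patch_by_id(self, region_id: int) -> RegionPatch:
        for p in self.patches:
            if p.region_id == region_id:
                return p
        raise KeyError(region_id)


def layout_geometry(partition: RegionPartition, rotation_deg: float = 0.0,
                    colors: dict[int, str] | None = None) -> BullseyeLayout:
    """Wedge geometry for a partition; ``rotation_deg`` rotates the whole
    diagram (the display orientation is configurable, anchor at 0 deg)."""
    patches = []
    for b in partition.bins:
        inner, outer = RING_RADII[b.level]
        if b.level == APEX:
            patches.append(RegionPatch(b.region_id, b.level, 0.0, 360.0, inner, outer))
        else:
            patches.append(
                RegionPatch(b.region_id, b.level,
                            (b.start_deg + rotation_deg) % 360.0,
                            (b.start_deg + rotation_deg) % 360.0 + (b.end_deg - b.start_deg),
                            inner, outer)
            )
    return BullseyeLayout(mode=partition.mode, patches=patches,
                          colors=dict(colors or DEFAULT_COLORS))


def render_bullseye(
    severity: SeverityMap,
    partition: RegionPartition,
    out_path: str,
    rotation_deg: float = 0.0,
    labels: bool = False,
    legend: bool = True,
    colors: dict[int, str] | None = None,
) -> BullseyeLayout:
    """Render one wedge per region filled by its severity color.

    The severity map and the partition must share mode and region ids.
    Returns the layout used, so callers can probe wedge centroids.
    """
    if severity.mode != partition.mode:
        raise ValueError(
            f"mode mismatch: severity map is {severity.mode}, partition is {partition.mode}"
        )
    missing = set(partition.region_ids) - set(severity.scores)
    if missing:
        raise ValueError(f"severity map is missing regions {sorted(missing)}")
    layout = layout_geometry(partition, rotation_deg, colors)
    # axes fill the canvas so data coords map linearly onto pixels (probe-able)
    fig = plt.figure(figsize=(6, 6), dpi=100)
    ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
    ax.set_aspect("equal")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.axis("off")
    for p in layout.patches:
        color = layout.colors[severity.scores[p.region_id]]
        if p.level == APEX:
            ax.add_patch(Circle((0, 0), p.outer_frac, facecolor=color,
                                edgecolor="black", linewidth=0.8))
        else:
            ax.add_patch(Wedge((0, 0), p.outer_frac, p.start_deg, p.end_deg,
                               width=p.outer_frac - p.inner_frac, facecolor=color,
                               edgecolor="black", linewidth=0.8))
        if labels and p.level != APEX:
            x, y = p.centroid
            ax.text(x, y, str(p.region_id), ha="center", va="center", fontsize=5)
    if legend:
        handles = [
            plt.Line2D([], [], marker="s", linestyle="", markersize=10,
                       markerfacecolor=layout.colors[s], markeredgecolor="black",
                       label=f"{s}: {CLASS_NAMES[s]}")
            for s in range(4)
        ]
        ax.legend(handles=handles, loc="upper right", fontsize=7, frameon=False)
    with matplotlib.rc_context({"svg.hashsalt": "lvhquant"}):
        fig.savefig(out_path, bbox_inches=None, metadata=(
            {"Date": None} if out_path.endswith(".svg") else None))
    plt.close(fig)
    return layout


def probe_pixel(layout_patch: RegionPatch, image_shape: tuple[int, int]) -> tuple[int, int]:
    """Pixel (row, col) of a wedge centroid in a figure rendered by
    :func:`render_bullseye` at default size (600x600 px, data range +-1.3)."""
    x, y = layout_patch.centroid
    h, w = image_shape[0], image_shape[1]
    col = int(round((x + 1.3) / 2.6 * (w - 1)))
    row = int(round((1.3 - y) / 2.6 * (h - 1)))
    return row, col
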