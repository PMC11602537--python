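"""Within-row plant-distribution assessment.

From the detected (or annotated) boxes of a plot, plant centroids are
computed, sorted along the row axis, and consecutive center-to-center
distances are converted to centimeters through the ground sample distance.
Pairs closer than 4 cm are flagged as jointed (doubles/triples), gaps wider
than 15 cm are flagged as missing plants, and a plot with fewer than 10
flagged instances overall is considered of acceptable quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .standcount import AnnotationSet

JOINTED_CM = 4.0
GAP_CM = 15.0
MAX_FLAGGED_ACCEPTABLE = 10


@dataclass
class PlantLayout:
    plot_id: str
    points: np.ndarray            # (n, 2) centroid pixels (x, y)
    gsd_cm: float
    distances_cm: np.ndarray      # consecutive neighbor distances, row order
    flags: list[str]              # jointed | normal | gap, one per pair
    quality: str                  # acceptable | poor

    @property
    def n_plants(self) -> int:
        return len(self.points)

    @property
    def n_jointed(self) -> int:
        return self.flags.count("jointed")

    @property
    def n_gaps(self) -> int:
        return self.flags.count("gap")


def centroids(boxes: AnnotationSet | list) -> np.ndarray:
    """Box centers (x + w/2, y + h/2) as an (n, 2) array."""
    items = boxes.boxes if isinstance(boxes, AnnotationSet) else boxes
    if not items:
        return np.empty((0, 2))
    return np.array([b.center for b in items], dtype=float)


def neighbor_distances(points: np.ndarray, gsd_cm: float,
                       row_axis: int | None = None,
                       projected: bool = False) -> np.ndarray:
    """Euclidean distances (cm) between row-consecutive plant centers.

    Points are ordered along ``row_axis`` (0 = x, 1 = y); when None, the axis
    with the larger coordinate spread is taken as the row direction (plots
    are much longer along the row).  ``projected`` measures along the row
    axis only instead of the full Euclidean distance.
    """
    if gsd_cm <= 0:
        raise ValueError("gsd_cm must be > 0")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        return np.empty(0)
    if row_axis is None:
        spread = points.max(axis=0) - points.min(axis=0)
        row_axis = int(np.argmax(spread))
    order = np.argsort(points[:, row_axis], kind="stable")
    sorted_pts = points[order]
    deltas = np.diff(sorted_pts, axis=0)
    if projected:
        d = np.abs(deltas[:, row_axis])
    else:
        d = np.hypot(deltas[:, 0], deltas[:, 1])
    return d * gsd_cm


def flag_spacing(distances_cm: np.ndarray, low: float = JOINTED_CM,
                 high: float = GAP_CM) -> tuple[list[str], dict]:
    """Per-gap flags and a summary; d < low -> jointed, d > high -> gap.

    Boundary values (exactly 4 or 15 cm) are normal, matching the strict
    inequalities of the flagging rule.  The quality label is "acceptable"
    when the total flagged instances stay below 10, else "poor".
    """
    if low >= high:
        raise ValueError("low threshold must be below high threshold")
    distances_cm = np.asarray(distances_cm, dtype=float)
    flags = ["jointed" if d < low else "gap" if d > high else "normal"
             for d in distances_cm]
    n_jointed = flags.count("jointed")
    n_gaps = flags.count("gap")
    summary = {
        "n_pairs": len(flags),
        "n_jointed": n_jointed,
        "n_gaps": n_gaps,
        "n_flagged": n_jointed + n_gaps,
        "quality": "acceptable" if n_jointed + n_gaps < MAX_FLAGGED_ACCEPTABLE else "poor",
    }
    return flags, summary


def assess_layout(boxes: AnnotationSet, gsd_cm: float,
                  low: float = JOINTED_CM, high: float = GAP_CM,
                  row_axis: int | None = None) -> PlantLayout:
    """Full per-plot assessment: centroids -> distances -> flags -> quality."""
    pts = centroids(boxes)
    dists = neighbor_distances(pts, gsd_cm, row_axis=row_axis)
    flags, summary = flag_spacing(dists, low=low, high=high)
    return PlantLayout(plot_id=boxes.plot_id, points=pts, gsd_cm=gsd_cm,
                       distances_cm=dists, flags=flags, quality=summary["quality"])


def layout_table(layouts: list[PlantLayout]) -> pd.DataFrame:
    """Summary CSV table: plot_id, n_plants, n_jointed, n_gaps, quality."""
    return pd.DataFrame([{"plot_id": l.plot_id, "n_plants": l.n_plants,
                          "n_jointed": l.n_jointed, "n_gaps": l.n_gaps,
                          "quality": l.quality} for l in layouts])
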