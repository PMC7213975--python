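"""Scoring of the four behavioral assays.

Assays and readouts:

* Elevated plus maze (EPM): percent of scored time in the open arms
  (center zone counts in neither arm but stays in the denominator).
* Open field: total path length (cm) after median-filter despiking.
* Three-chamber sociability: chamber occupancy times for the conspecific
  (C) and empty-cage (E) sides, approach counts into a 5-cm disc around
  each holding cage, and the preference indices (x_C - x_E)/(x_C + x_E).
* Marble burying: percent of 12 marbles whose exposed surface area
  (before vs after, from binary image masks) dropped by at least 2/3.

Positions are body centroids in cm, origin at the arena corner, y up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, box

__all__ = [
    "Trajectory",
    "ArenaGeometry",
    "SociabilityResult",
    "MarbleResult",
    "preference_index",
    "score_epm",
    "score_open_field",
    "score_sociability",
    "score_marbles",
]

APPROACH_RADIUS_CM = 5.0
HYSTERESIS_RADIUS_CM = 7.0  # must exit this far before a re-entry counts
BURIED_AREA_FRACTION = 2.0 / 3.0
N_MARBLES = 12
MAX_GAP_S = 1.0


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def sample_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample occupancy weight (s) and a validity mask.

        Each sample owns the time until the next one; gaps longer than
        ``MAX_GAP_S`` are excluded from scoring. The final sample gets
        the median step.
        """
        dt = np.diff(self.t)
        med = float(np.median(dt)) if dt.size else 0.0
        w = np.append(dt, med)
        valid = w <= MAX_GAP_S
        return w, valid


@dataclass(frozen=True)
class ArenaGeometry:
    """Named zone polygons for one assay arena."""

    kind: str
    zones: dict[str, Polygon]
    cage_centers: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def epm(cls, arm_length: float = 30.0, arm_width: float = 5.0) -> "ArenaGeometry":
        """Plus maze centered at origin: open arms on x, closed arms on y."""
        h = arm_width / 2.0
        zones = {
            "open_east": box(h, -h, h + arm_length, h),
            "open_west": box(-h - arm_length, -h, -h, h),
            "closed_north": box(-h, h, h, h + arm_length),
            "closed_south": box(-h, -h - arm_length, h, -h),
            "center": box(-h, -h, h, h),
        }
        return cls(kind="epm", zones=zones)

    @classmethod
    def open_field(cls, side: float = 30.0) -> "ArenaGeometry":
        """Square box divided into nine equal quadrants."""
        s = side / 3.0
        zones = {
            f"q{r}{c}": box(c * s, r * s, (c + 1) * s, (r + 1) * s)
            for r in range(3)
            for c in range(3)
        }
        return cls(kind="open_field", zones=zones)

    @classmethod
    def three_chamber(
        cls,
        width: float = 60.0,
        depth: float = 40.0,
        conspecific_side: str = "left",
    ) -> "ArenaGeometry":
        """Three equal chambers along x; holding cages centered in the side
        chambers, the conspecific's on ``conspecific_side``."""
        if conspecific_side not in ("left", "right"):
            raise ValueError("conspecific_side must be 'left' or 'right'")
        w = width / 3.0
        zones = {
            "left": box(0, 0, w, depth),
            "center": box(w, 0, 2 * w, depth),
            "right": box(2 * w, 0, width, depth),
        }
        cages = {"left": (w / 2.0, depth / 2.0), "right": (width - w / 2.0, depth / 2.0)}
        centers = {
            "conspecific": cages[conspecific_side],
            "empty": cages["right" if conspecific_side == "left" else "left"],
        }
        return cls(kind="three_chamber", zones=zones, cage_centers=centers)

    def occupancy(self, traj: Trajectory) -> dict[str, float]:
        """Seconds spent in each zone (gap-excluded)."""
        w, valid = traj.sample_weights()
        out = {}
        for name, poly in self.zones.items():
            inside = shapely.contains_xy(poly, traj.x, traj.y)
            out[name] = float(w[inside & valid].sum())
        return out


@dataclass(frozen=True)
class SociabilityResult:
    time_c: float
    time_e: float
    app_c: int
    app_e: int
    time_center: float = 0.0

    @property
    def time_index(self) -> float:
        return preference_index(self.time_c, self.time_e)

    @property
    def approach_index(self) -> float:
        return preference_index(float(self.app_c), float(self.app_e))


@dataclass(frozen=True)
class MarbleResult:
    percent_buried: float
    n_detected: int
    buried_flags: tuple[bool, ...]
    area_ratios: tuple[float, ...]  # exposed-after / exposed-before per marble


def preference_index(a: float, b: float) -> float:
    """(a - b)/(a + b) for non-negative a, b; NaN when both are zero."""
    if a < 0 or b < 0:
        raise ValueError("preference_index requires non-negative inputs")
    if a + b == 0:
        return float("nan")
    return (a - b) / (a + b)


def score_epm(traj: Trajectory, geom: ArenaGeometry) -> float:
    """Percent of scored time spent in the open arms."""
    if geom.kind != "epm":
        raise ValueError("geometry is not an EPM arena")
    occ = geom.occupancy(traj)
    _, valid = traj.sample_weights()
    w, _ = traj.sample_weights()
    scored = float(w[valid].sum())
    if scored <= 0:
        raise ValueError("no scorable samples")
    open_time = sum(v for k, v in occ.items() if k.startswith("open"))
    return 100.0 * open_time / scored


def score_open_field(traj: Trajectory, despike_window: int = 5) -> float:
    """Total distance traversed (cm) after median-filter despiking."""
    if traj.t.size < 2:
        raise ValueError("need at least two samples")
    x = ndimage.median_filter(traj.x, size=despike_window, mode="nearest")
    y = ndimage.median_filter(traj.y, size=despike_window, mode="nearest")
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def _count_approaches(
    traj: Trajectory,
    center: tuple[float, float],
    radius: float,
    hysteresis_radius: float,
) -> int:
    """Entries into the approach disc, debounced by the hysteresis radius.

    Continuous presence inside the disc is one approach; after leaving,
    a new approach is counted only once the animal has been farther than
    ``hysteresis_radius`` away.
    """
    d = np.hypot(traj.x - center[0], traj.y - center[1])
    count, armed = 0, True
    for di in d:
        if armed and di <= radius:
            count += 1
            armed = False
        elif not armed and di > hysteresis_radius:
            armed = True
    return count


def score_sociability(
    traj: Trajectory,
    geom: ArenaGeometry,
    approach_radius_cm: float = APPROACH_RADIUS_CM,
    hysteresis_radius_cm: float = HYSTERESIS_RADIUS_CM,
) -> SociabilityResult:
    """Chamber-occupancy times and cage approaches for the free phase.

    Time_C/Time_E are occupancies of the side chambers (conspecific vs
    empty cage); approaches are debounced entries into the 5-cm disc
    around each cage.
    """
    if geom.kind != "three_chamber":
        raise ValueError("geometry is not a three-chamber arena")
    occ = geom.occupancy(traj)
    c_zone = "left" if geom.cage_centers["conspecific"][0] < geom.cage_centers["empty"][0] else "right"
    e_zone = "right" if c_zone == "left" else "left"
    return SociabilityResult(
        time_c=occ[c_zone],
        time_e=occ[e_zone],
        time_center=occ["center"],
        app_c=_count_approaches(
            traj, geom.cage_centers["conspecific"], approach_radius_cm, hysteresis_radius_cm
        ),
        app_e=_count_approaches(
            traj, geom.cage_centers["empty"], approach_radius_cm, hysteresis_radius_cm
        ),
    )


def score_marbles(
    before_mask: np.ndarray,
    after_mask: np.ndarray,
    buried_threshold: float = BURIED_AREA_FRACTION,
    n_expected: int = N_MARBLES,
) -> MarbleResult:
    """Percent of marbles buried, from before/after exposed-area masks.

    Connected components of the before mask are the marbles; each is
    matched to after-mask components by centroid proximity (unmatched
    marbles are fully buried). A marble counts as buried when its exposed
    area decreased by at least ``buried_threshold``.
    """
    before = np.asarray(before_mask).astype(bool)
    after = np.asarray(after_mask).astype(bool)
    if before.shape != after.shape:
        raise ValueError("masks must share a frame")
    lab_b, n_b = ndimage.label(before)
    if n_b == 0:
        raise ValueError("no marbles detected in the before mask")
    if n_b != n_expected:
        warnings.warn(
            f"expected {n_expected} marbles, detected {n_b}; proceeding", stacklevel=2
        )
    lab_a, n_a = ndimage.label(after)
    idx_b = np.arange(1, n_b + 1)
    areas_b = ndimage.sum_labels(before, lab_b, idx_b)
    cent_b = np.array(ndimage.center_of_mass(before, lab_b, idx_b))
    if n_a:
        idx_a = np.arange(1, n_a + 1)
        areas_a = ndimage.sum_labels(after, lab_a, idx_a)
        cent_a = np.array(ndimage.center_of_mass(after, lab_a, idx_a))
    # match radius: one marble diameter, from the median before-area
    match_r = 2.0 * np.sqrt(np.median(areas_b) / np.pi)

    ratios, flags = [], []
    for area, cen in zip(areas_b, cent_b):
        exposed = 0.0
        if n_a:
            dist = np.hypot(cent_a[:, 0] - cen[0], cent_a[:, 1] - cen[1])
            j = int(np.argmin(dist))
            if dist[j] <= match_r:
                exposed = float(areas_a[j])
        ratio = exposed / float(area)
        ratios.append(ratio)
        flags.append((1.0 - ratio) >= buried_threshold)
    percent = 100.0 * sum(flags) / n_b
    return MarbleResult(
        percent_buried=percent,
        n_detected=int(n_b),
        buried_flags=tuple(flags),
        area_ratios=tuple(ratios),
    )
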