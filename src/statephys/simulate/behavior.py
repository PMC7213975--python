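"""Synthetic behavioral sessions with planted preferences.

Trajectories are reflected random walks inside the arena: the animal
dwells in a target zone for a block of time, wanders within it (steps
reflected at the zone walls), then picks the next target zone with
probabilities that encode the planted occupancy preference. Marble-assay
masks are binary rasters in which each "after" marble keeps a concentric
exposed disc whose area implements a chosen coverage fraction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from ..behavior import ArenaGeometry, Trajectory

__all__ = [
    "gen_epm_trajectory",
    "gen_open_field_trajectory",
    "gen_three_chamber_trajectory",
    "gen_marble_masks",
]

EPM_DURATION_S = 300.0  # 5-min session
OPEN_FIELD_DURATION_S = 1200.0  # 20-min session
SOCIABILITY_DURATION_S = 600.0  # 10-min free-exploration phase
TRACK_FS_HZ = 5.0


def _reflect(val: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the walls."""
    span = hi - lo
    val = np.mod(val - lo, 2 * span)
    return lo + np.where(val > span, 2 * span - val, val)


def _walk_in_zone(
    rng: np.random.Generator,
    poly: Polygon,
    start: tuple[float, float] | None,
    n_steps: int,
    step_sd: float,
    attractor: tuple[float, float] | None = None,
    pull: float = 0.0,
) -> np.ndarray:
    """Reflected random walk within a rectangular zone."""
    minx, miny, maxx, maxy = poly.bounds
    pos = np.empty((n_steps, 2))
    if start is None:
        start = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
    p = np.array(start, dtype=float)
    p[0] = _reflect(np.array([p[0]]), minx, maxx)[0]
    p[1] = _reflect(np.array([p[1]]), miny, maxy)[0]
    for i in range(n_steps):
        step = rng.normal(0.0, step_sd, size=2)
        if attractor is not None and pull > 0:
            step += pull * (np.asarray(attractor) - p)
        p = p + step
        p[0] = _reflect(np.array([p[0]]), minx, maxx)[0]
        p[1] = _reflect(np.array([p[1]]), miny, maxy)[0]
        pos[i] = p
    return pos


def _dwell_walk(
    rng: np.random.Generator,
    geom: ArenaGeometry,
    zone_seq: list[str],
    dwell_s: float,
    fs: float,
    step_sd: float,
    attractors: dict[str, tuple[float, float]] | None = None,
    pull: float = 0.0,
) -> Trajectory:
    n_per = int(round(dwell_s * fs))
    chunks = []
    prev_end = None
    for zone in zone_seq:
        poly = geom.zones[zone]
        att = (attractors or {}).get(zone)
        chunks.append(
            _walk_in_zone(rng, poly, prev_end, n_per, step_sd, attractor=att, pull=pull)
        )
        prev_end = None  # jump: dwell blocks restart at a random point in the new zone
    pos = np.vstack(chunks)
    t = np.arange(pos.shape[0]) / fs
    return Trajectory(t=t, x=pos[:, 0], y=pos[:, 1])


def gen_epm_trajectory(
    open_frac: float,
    geom: ArenaGeometry | None = None,
    duration_s: float = EPM_DURATION_S,
    fs: float = TRACK_FS_HZ,
    dwell_s: float = 10.0,
    step_sd_cm: float = 1.5,
    seed: int = 0,
) -> tuple[Trajectory, ArenaGeometry]:
    """EPM walk with planted open-arm occupancy ``open_frac``."""
    if not 0 <= open_frac <= 1:
        raise ValueError("open_frac must lie in [0, 1]")
    geom = geom or ArenaGeometry.epm()
    rng = np.random.default_rng(seed)
    n_blocks = max(1, int(round(duration_s / dwell_s)))
    opens = ["open_east", "open_west"]
    closeds = ["closed_north", "closed_south"]
    seq = [
        rng.choice(opens) if rng.uniform() < open_frac else rng.choice(closeds)
        for _ in range(n_blocks)
    ]
    return _dwell_walk(rng, geom, seq, dwell_s, fs, step_sd_cm), geom


def gen_open_field_trajectory(
    duration_s: float = OPEN_FIELD_DURATION_S,
    side_cm: float = 30.0,
    fs: float = TRACK_FS_HZ,
    step_sd_cm: float = 1.5,
    seed: int = 0,
) -> tuple[Trajectory, ArenaGeometry]:
    """Reflected random walk across the whole open-field box."""
    geom = ArenaGeometry.open_field(side_cm)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    pos = np.empty((n, 2))
    p = np.array([side_cm / 2.0, side_cm / 2.0])
    for i in range(n):
        p = p + rng.normal(0.0, step_sd_cm, size=2)
        p[0] = _reflect(np.array([p[0]]), 0.0, side_cm)[0]
        p[1] = _reflect(np.array([p[1]]), 0.0, side_cm)[0]
        pos[i] = p
    t = np.arange(n) / fs
    return Trajectory(t=t, x=pos[:, 0], y=pos[:, 1]), geom


def gen_three_chamber_trajectory(
    time_pref_index: float,
    geom: ArenaGeometry | None = None,
    duration_s: float = SOCIABILITY_DURATION_S,
    fs: float = TRACK_FS_HZ,
    dwell_s: float = 15.0,
    center_frac: float = 0.2,
    step_sd_cm: float = 2.0,
    cage_pull: float = 0.05,
    seed: int = 0,
) -> tuple[Trajectory, ArenaGeometry]:
    """Three-chamber walk with a planted side-time preference index.

    Side dwell blocks choose the conspecific chamber with probability
    (1 + index)/2, so the expected chamber-time index equals the planted
    value. A weak pull toward each side chamber's cage makes approach
    counts track chamber visits.
    """
    if not -1 <= time_pref_index <= 1:
        raise ValueError("time_pref_index must lie in [-1, 1]")
    geom = geom or ArenaGeometry.three_chamber()
    rng = np.random.default_rng(seed)
    c_zone = "left" if geom.cage_centers["conspecific"][0] < geom.cage_centers["empty"][0] else "right"
    e_zone = "right" if c_zone == "left" else "left"
    n_blocks = max(1, int(round(duration_s / dwell_s)))
    p_c = (1.0 + time_pref_index) / 2.0
    seq = []
    for _ in range(n_blocks):
        if rng.uniform() < center_frac:
            seq.append("center")
        else:
            seq.append(c_zone if rng.uniform() < p_c else e_zone)
    attractors = {
        c_zone: geom.cage_centers["conspecific"],
        e_zone: geom.cage_centers["empty"],
    }
    traj = _dwell_walk(
        rng, geom, seq, dwell_s, fs, step_sd_cm, attractors=attractors, pull=cage_pull
    )
    return traj, geom


def gen_marble_masks(
    coverage_fractions: np.ndarray | list[float],
    shape: tuple[int, int] = (180, 240),
    marble_radius_px: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Before/after exposed-area masks for the marble-burying assay.

    One marble per coverage fraction (12 expected), laid out on a grid.
    The after-mask keeps, for each marble, a concentric disc whose area is
    (1 - coverage) of the original, so area ratios are analytic.
    """
    cov = np.asarray(coverage_fractions, dtype=float)
    if np.any((cov < 0) | (cov > 1)):
        raise ValueError("coverage fractions must lie in [0, 1]")
    n = cov.size
    n_cols = int(np.ceil(np.sqrt(n * shape[1] / shape[0])))
    n_rows = int(np.ceil(n / n_cols))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    before = np.zeros(shape, dtype=bool)
    after = np.zeros(shape, dtype=bool)
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if k >= n:
                break
            cy = (r + 0.5) * shape[0] / n_rows
            cx = (c + 0.5) * shape[1] / n_cols
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            before |= d2 <= marble_radius_px**2
            r_after = marble_radius_px * np.sqrt(max(0.0, 1.0 - cov[k]))
            if r_after > 0:
                after |= d2 <= r_after**2
            k += 1
    return before, after
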