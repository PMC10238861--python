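"""Crocker–Grier-style spot detection and trajectory linking.

Candidate peaks are found on a bandpassed image (Gaussian smoothing minus
a boxcar background at the feature size), refined to subpixel precision by
iterative intensity-weighted centroiding inside the feature window, and
linked frame-to-frame by minimising the total squared displacement over
candidate pairs within the allowed per-frame displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .particle_sim import TRAJECTORY_COLUMNS, ImageStack, TrajectorySet

__all__ = ["TrackingParams", "detect_spots", "link_tracks", "track_stack"]


@dataclass(frozen=True)
class TrackingParams:
    """Detection/linking parameters, pixel and frame units."""

    feature_size: int = 7
    intensity_threshold: float = 1.0
    min_separation: float = 2.0
    max_displacement: float = 4.0
    memory: int = 0
    min_track_length: int = 11

    def __post_init__(self) -> None:
        if self.feature_size < 3 or self.feature_size % 2 == 0:
            raise ValueError("feature_size must be odd and >= 3")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")


def _bandpass(frame: np.ndarray, feature_size: int) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(frame, 1.0)
    background = ndimage.uniform_filter(frame, feature_size)
    return np.clip(smoothed - background, 0, None)


def _refine_centroid(img: np.ndarray, x: float, y: float, radius: int,
                     max_iter: int = 10, tol: float = 1e-3) -> tuple[float, float, float]:
    """Iterative intensity-weighted centroid within a square feature window."""
    ny, nx = img.shape
    for _ in range(max_iter):
        ix, iy = int(round(x)), int(round(y))
        x0, x1 = max(ix - radius, 0), min(ix + radius + 1, nx)
        y0, y1 = max(iy - radius, 0), min(iy + radius + 1, ny)
        win = img[y0:y1, x0:x1]
        total = win.sum()
        if total <= 0:
            break
        gy, gx = np.mgrid[y0:y1, x0:x1]
        new_x = float((win * gx).sum() / total)
        new_y = float((win * gy).sum() / total)
        if np.hypot(new_x - x, new_y - y) < tol:
            x, y = new_x, new_y
            break
        x, y = new_x, new_y
    mass = float(win.sum()) if "win" in locals() else 0.0
    return x, y, mass


def detect_spots(frame: np.ndarray, params: TrackingParams) -> pd.DataFrame:
    """Detect spots in one frame; returns columns ``x_px, y_px, intensity``.

    Peaks on the bandpassed image above ``intensity_threshold`` are refined
    to subpixel centres; detections closer than ``min_separation`` are
    merged, keeping the brighter one.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite pixels")

    bp = _bandpass(frame, params.feature_size)
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        bp,
        min_distance=max(int(round(params.min_separation)), 1),
        threshold_abs=params.intensity_threshold,
        exclude_border=False,
    )
    radius = params.feature_size // 2
    rows = []
    for yc, xc in coords:
        x, y, mass = _refine_centroid(bp, float(xc), float(yc), radius)
        rows.append((x, y, mass))
    if not rows:
        return pd.DataFrame(columns=["x_px", "y_px", "intensity"])
    det = pd.DataFrame(rows, columns=["x_px", "y_px", "intensity"])

    # merge near-coincident detections, brighter one wins
    det = det.sort_values("intensity", ascending=False).reset_index(drop=True)
    tree = cKDTree(det[["x_px", "y_px"]].to_numpy())
    keep = np.ones(len(det), dtype=bool)
    for i in range(len(det)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(det.loc[i, ["x_px", "y_px"]].to_numpy(),
                                       params.min_separation):
            if j > i:
                keep[j] = False
    return det[keep].reset_index(drop=True)


def _assign(prev: np.ndarray, curr: np.ndarray, max_disp: float) -> list[tuple[int, int]]:
    """Frame-pair assignment minimising total squared displacement.

    Uses the Hungarian algorithm on an augmented cost matrix where leaving a
    particle unmatched (track end / track birth) costs ``max_disp**2``.
    Returns (prev_index, curr_index) matches.
    """
    n, m = len(prev), len(curr)
    if n == 0 or m == 0:
        return []
    big = 1e12
    death = max_disp**2
    cost = np.full((n + m, m + n), big)
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
    d2 = np.where(d2 <= max_disp**2, d2, big)
    cost[:n, :m] = d2
    cost[np.arange(n) + 0, np.arange(n) + m] = death  # unmatched prev
    cost[np.arange(m) + n, np.arange(m)] = death      # unmatched curr
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(r, c) for r, c in zip(rows, cols)
            if r < n and c < m and cost[r, c] < big]


def link_tracks(detections: list[pd.DataFrame], params: TrackingParams,
                pixel_size: float = 1.0, frame_interval: float = 1.0) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    ``detections`` is one DataFrame (columns ``x_px, y_px, intensity``) per
    frame, in frame order. With ``memory = 0`` an unmatched particle ends
    its track. Tracks shorter than ``min_track_length`` are discarded, and
    positions are converted to µm.
    """
    if params.memory > 0:
        raise NotImplementedError("gap closing (memory > 0) is not supported")

    next_id = 0
    active: dict[int, tuple[float, float]] = {}
    rows: list[tuple] = []

    for f, det in enumerate(detections):
        pts = det[["x_px", "y_px"]].to_numpy() if len(det) else np.empty((0, 2))
        ids = sorted(active)  # deterministic candidate order (ties -> lower id)
        prev = np.array([active[i] for i in ids]) if ids else np.empty((0, 2))
        matches = _assign(prev, pts, params.max_displacement)
        matched_prev = {ids[r] for r, _ in matches}
        matched_curr = {c for _, c in matches}
        new_active: dict[int, tuple[float, float]] = {}
        for r, c in matches:
            pid = ids[r]
            new_active[pid] = (pts[c, 0], pts[c, 1])
            rows.append((pid, f, pts[c, 0], pts[c, 1], det["intensity"].iloc[c]))
        for c in range(len(pts)):
            if c not in matched_curr:
                pid = next_id
                next_id += 1
                new_active[pid] = (pts[c, 0], pts[c, 1])
                rows.append((pid, f, pts[c, 0], pts[c, 1], det["intensity"].iloc[c]))
        active = new_active  # unmatched previous particles terminate

    df = pd.DataFrame(rows, columns=["particle_id", "frame", "x_px", "y_px", "intensity"])
    if len(df):
        lengths = df.groupby("particle_id")["frame"].size()
        df = df[df["particle_id"].map(lengths) >= params.min_track_length]
    df = df.assign(
        x_um=df["x_px"] * pixel_size,
        y_um=df["y_px"] * pixel_size,
        time_s=df["frame"] * frame_interval,
    )[TRAJECTORY_COLUMNS].sort_values(["frame", "particle_id"], kind="stable")
    return TrajectorySet(df.reset_index(drop=True), provenance="tracked")


def track_stack(stack: ImageStack, params: TrackingParams) -> TrajectorySet:
    """Detect and link spots across a whole image stack.

    Positions are reported in the stack's physical coordinates (µm),
    honouring the stack origin so tracked output is directly comparable to
    simulated ground truth.
    """
    detections = [detect_spots(frame, params) for frame in stack.frames]
    traj = link_tracks(detections, params, pixel_size=stack.pixel_size,
                       frame_interval=stack.frame_interval)
    ox, oy = stack.origin
    traj.data["x_um"] += ox
    traj.data["y_um"] += oy
    return traj
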