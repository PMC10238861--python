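"""Stochastic simulation of membrane particles and synthetic movie rendering.

Particles diffuse laterally in the membrane plane, are advected by a
prescribed velocity, and exchange with a cytoplasmic pool: each particle
carries an exponentially distributed membrane residence time (rate
``k_off``), and when it dissociates it is immediately replaced by a new
particle at a uniform-random position, so the number of membrane particles
per frame is constant. Trajectories can be rendered as near-TIRF-like
two-channel movies (PSF-blurred spots on a noisy background, plus a
flow-warped speckle "cortex" channel) so that the downstream detection,
tracking and PIV stages can be benchmarked against known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "TrajectorySet",
    "ImageStack",
    "simulate_trajectories",
    "render_images",
    "render_cortex_texture",
]

#: pixels added on every side of the rendered field of view, beyond the
#: maximal particle displacement, so wandering particles are never clipped
RENDER_PAD_PX = 6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the particle simulation and renderer.

    Lengths are µm, times are s, velocities µm/s, diffusivities µm²/s.
    ``v_parallel`` is drift along the long (x) axis, ``v_perpendicular``
    along the short (y) axis. ``cv_D`` is the coefficient of variation of
    the per-particle diffusivity (drawn once per particle, log-normal).
    """

    n_particles: int = 100
    D: float = 0.1
    cv_D: float = 0.0
    k_off: float = 0.0
    v_parallel: float = 0.0
    v_perpendicular: float = 0.0
    frame_interval: float = 0.1
    duration: float = 100.0
    long_axis: float = 30.0
    short_axis: float = 20.0
    pixel_size: float = 0.1
    psf_sigma: float = 1.3
    background_mean: float = 100.0
    background_noise_sd: float = 5.0
    spot_amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        for name in ("D", "k_off", "cv_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must cover at least one frame interval")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.long_axis <= 0 or self.short_axis <= 0:
            raise ValueError("field of view axes must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


TRAJECTORY_COLUMNS = ["particle_id", "frame", "time_s", "x_um", "y_um", "intensity"]


@dataclass
class TrajectorySet:
    """Per-particle, per-frame subpixel positions in physical units.

    ``data`` holds one row per (particle, frame) with columns
    ``particle_id, frame, time_s, x_um, y_um, intensity``. ``provenance``
    records whether positions are simulated ground truth or tracked.
    """

    data: pd.DataFrame
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        if not np.isfinite(self.data[["x_um", "y_um"]].to_numpy()).all():
            raise ValueError("trajectory positions must be finite")
        frames = self.data.groupby("particle_id")["frame"]
        if (frames.apply(lambda f: np.any(np.diff(f.to_numpy()) <= 0))).any():
            raise ValueError("frames within a particle must be strictly increasing")

    @property
    def n_particles(self) -> int:
        return self.data["particle_id"].nunique()

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "file") -> "TrajectorySet":
        return cls(pd.read_csv(path), provenance=provenance)


@dataclass
class ImageStack:
    """A (t, y, x) stack of intensity counts with physical calibration."""

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""
    #: physical coordinate (µm) of the center of pixel (0, 0), so rendered
    #: stacks can be mapped back onto trajectory coordinates
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (t, y, x) array")
        if self.frames.shape[1] == 0 or self.frames.shape[2] == 0:
            raise ValueError("image stack has zero spatial extent")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def to_tiff(self, path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar with calibration."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32),
                         photometric="minisblack")
        sidecar = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "channel": self.channel,
            "origin_um": list(self.origin),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path, pixel_size: Optional[float] = None,
                  frame_interval: Optional[float] = None) -> "ImageStack":
        import tifffile

        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            frames=frames,
            pixel_size=pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0),
            frame_interval=frame_interval if frame_interval is not None else meta.get("frame_interval_s", 1.0),
            channel=meta.get("channel", ""),
            origin=tuple(meta.get("origin_um", (0.0, 0.0))),
        )


def _draw_diffusivities(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    """Per-particle diffusivity: log-normal with mean D and CV cv_D."""
    if config.cv_D == 0 or config.D == 0:
        return np.full(n, config.D)
    sigma2 = np.log1p(config.cv_D**2)
    mu = np.log(config.D) - sigma2 / 2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _lifetime_frames(rng: np.random.Generator, k_off: float, dt: float) -> tuple[int, float]:
    """Frames a particle occupies before dissociating, plus the drawn
    continuous lifetime (s).

    A particle born at a frame time survives the frames falling inside its
    exponential lifetime; it is visible for at least one frame.
    """
    if k_off == 0:
        return np.iinfo(np.int64).max, np.inf
    life = rng.exponential(1.0 / k_off)
    return int(life / dt) + 1, life


def simulate_trajectories(config: SimulationConfig) -> tuple[TrajectorySet, pd.DataFrame]:
    """Simulate membrane particle trajectories at constant occupancy.

    Every frame contains exactly ``n_particles`` live particles: when a
    particle's exponential lifetime ends, a fresh particle (new id, uniform
    random position) takes over its slot on the next frame. Per frame, each
    particle takes an isotropic Gaussian diffusive step (variance 2·D_i·Δt
    per axis, D_i drawn once per particle) plus the deterministic advective
    offset v·Δt.

    Returns the trajectory set and a ground-truth table with one row per
    particle id (``particle_id, D_um2_s, birth_frame, n_frames_alive``).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    n_frames = config.n_frames

    if config.k_off == 0:
        # no turnover: every slot is one particle for the whole movie, so
        # the walk vectorises over particles
        n = config.n_particles
        D_i = _draw_diffusivities(rng, config, n)
        x0 = rng.uniform(0, config.long_axis, n)
        y0 = rng.uniform(0, config.short_axis, n)
        sd = np.sqrt(2 * D_i * dt)
        steps = rng.normal(0.0, 1.0, size=(n, n_frames - 1, 2)) * sd[:, None, None]
        xs = x0[:, None] + np.concatenate(
            [np.zeros((n, 1)), np.cumsum(steps[:, :, 0] + config.v_parallel * dt, axis=1)], axis=1)
        ys = y0[:, None] + np.concatenate(
            [np.zeros((n, 1)), np.cumsum(steps[:, :, 1] + config.v_perpendicular * dt, axis=1)], axis=1)
        data = pd.DataFrame({
            "particle_id": np.repeat(np.arange(n, dtype=np.int64), n_frames),
            "frame": np.tile(np.arange(n_frames, dtype=np.int64), n),
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
        })
        data["time_s"] = data["frame"] * dt
        data["intensity"] = float(config.spot_amplitude)
        data = data[TRAJECTORY_COLUMNS].sort_values(["frame", "particle_id"],
                                                    kind="stable").reset_index(drop=True)
        truth_df = pd.DataFrame({
            "particle_id": np.arange(n, dtype=np.int64),
            "D_um2_s": D_i,
            "birth_frame": np.zeros(n, dtype=np.int64),
            "n_frames_alive": np.full(n, n_frames, dtype=np.int64),
            "lifetime_s": np.full(n, np.inf),
        })
        return TrajectorySet(data, provenance="simulated"), truth_df

    rows_id: list[np.ndarray] = []
    rows_frame: list[np.ndarray] = []
    rows_x: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    truth: list[tuple] = []

    next_id = 0
    for _slot in range(config.n_particles):
        frame = 0
        while frame < n_frames:
            pid = next_id
            next_id += 1
            D_i = _draw_diffusivities(rng, config, 1)[0]
            life_frames, life_s = _lifetime_frames(rng, config.k_off, dt)
            alive = min(life_frames, n_frames - frame)
            x0 = rng.uniform(0, config.long_axis)
            y0 = rng.uniform(0, config.short_axis)
            sd = np.sqrt(2 * D_i * dt)
            steps = rng.normal(0.0, sd, size=(alive - 1, 2)) if alive > 1 else np.empty((0, 2))
            xs = x0 + np.concatenate([[0.0], np.cumsum(steps[:, 0] + config.v_parallel * dt)])
            ys = y0 + np.concatenate([[0.0], np.cumsum(steps[:, 1] + config.v_perpendicular * dt)])
            rows_id.append(np.full(alive, pid))
            rows_frame.append(np.arange(frame, frame + alive))
            rows_x.append(xs)
            rows_y.append(ys)
            truth.append((pid, D_i, frame, alive, life_s))
            frame += alive

    if rows_id:
        data = pd.DataFrame(
            {
                "particle_id": np.concatenate(rows_id).astype(np.int64),
                "frame": np.concatenate(rows_frame).astype(np.int64),
                "x_um": np.concatenate(rows_x),
                "y_um": np.concatenate(rows_y),
            }
        )
    else:
        data = pd.DataFrame({c: [] for c in ["particle_id", "frame", "x_um", "y_um"]})
    data["time_s"] = data["frame"] * dt
    data["intensity"] = float(config.spot_amplitude)
    data = data[TRAJECTORY_COLUMNS].sort_values(["frame", "particle_id"], kind="stable")
    data = data.reset_index(drop=True)
    truth_df = pd.DataFrame(
        truth,
        columns=["particle_id", "D_um2_s", "birth_frame", "n_frames_alive", "lifetime_s"],
    )
    return TrajectorySet(data, provenance="simulated"), truth_df


def _render_spots(shape, xs_px, ys_px, amplitudes, psf_sigma) -> np.ndarray:
    """Add Gaussian spots at subpixel positions onto a zero image."""
    img = np.zeros(shape)
    half = int(np.ceil(4 * psf_sigma))
    ny, nx = shape
    for x, y, amp in zip(xs_px, ys_px, amplitudes):
        ix, iy = int(round(x)), int(round(y))
        x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - x) ** 2) / (2 * psf_sigma**2))
        gy = np.exp(-((np.arange(y0, y1) - y) ** 2) / (2 * psf_sigma**2))
        img[y0:y1, x0:x1] += amp * gy[:, None] * gx[None, :]
    return img


def render_images(traj: TrajectorySet, config: SimulationConfig) -> ImageStack:
    """Render trajectories as PSF-blurred spots on a noisy background.

    The rendered area covers the nominal field of view extended to the
    largest particle excursion, padded by a further 6 px on every side, so
    particles that wander past the nominal edges remain inside the image.
    """
    df = traj.data
    px = config.pixel_size
    if len(df):
        x_min = min(0.0, df["x_um"].min())
        x_max = max(config.long_axis, df["x_um"].max())
        y_min = min(0.0, df["y_um"].min())
        y_max = max(config.short_axis, df["y_um"].max())
    else:
        x_min, x_max = 0.0, config.long_axis
        y_min, y_max = 0.0, config.short_axis

    nx = int(np.ceil((x_max - x_min) / px)) + 2 * RENDER_PAD_PX
    ny = int(np.ceil((y_max - y_min) / px)) + 2 * RENDER_PAD_PX
    # physical position of pixel-center (0, 0)
    origin = (x_min - (RENDER_PAD_PX - 0.5) * px, y_min - (RENDER_PAD_PX - 0.5) * px)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_frames = int(df["frame"].max()) + 1 if len(df) else config.n_frames
    frames = np.empty((n_frames, ny, nx), dtype=np.float64)
    by_frame = dict(tuple(df.groupby("frame"))) if len(df) else {}
    for f in range(n_frames):
        bg = rng.normal(config.background_mean, config.background_noise_sd, size=(ny, nx))
        sub = by_frame.get(f)
        if sub is not None and len(sub):
            xs_px = (sub["x_um"].to_numpy() - origin[0]) / px
            ys_px = (sub["y_um"].to_numpy() - origin[1]) / px
            bg += _render_spots((ny, nx), xs_px, ys_px, sub["intensity"].to_numpy(), config.psf_sigma)
        frames[f] = bg
    np.clip(frames, 0, None, out=frames)
    return ImageStack(frames, pixel_size=px, frame_interval=config.frame_interval,
                      channel="particles", origin=origin)


def render_cortex_texture(flow, config: SimulationConfig, n_frames: Optional[int] = None,
                          speckle_sigma: float = 2.0) -> ImageStack:
    """Render a flowing speckle texture emulating the cortical marker channel.

    A fixed random speckle image is warped frame-to-frame by the flow field
    (backward warp with subpixel interpolation), with fresh Gaussian noise
    added per frame. Raises if the flow exceeds half the smallest PIV
    interrogation window per frame, which would be untrackable.
    """
    px = config.pixel_size
    dt = config.frame_interval
    ny = int(round(config.short_axis / px))
    nx = int(round(config.long_axis / px))
    if n_frames is None:
        n_frames = config.n_frames

    yy, xx = np.mgrid[0:ny, 0:nx]
    x_um = (xx + 0.5) * px
    y_um = (yy + 0.5) * px

    t_mid = 0.0
    vx, vy = flow.sample(x_um.ravel(), y_um.ravel(), t_mid)
    speed_px = np.hypot(vx, vy).max() * dt / px
    if speed_px > 16:  # half of the smallest (32 px) interrogation window
        raise ValueError(
            f"flow speed {speed_px:.1f} px/frame exceeds the trackable range"
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    base = ndimage.gaussian_filter(rng.normal(size=(ny, nx)), speckle_sigma)
    base = (base - base.min()) / np.ptp(base)
    texture = base.copy()

    frames = np.empty((n_frames, ny, nx))
    amp = config.spot_amplitude
    for f in range(n_frames):
        noisy = (
            config.background_mean
            + amp * texture
            + rng.normal(0, config.background_noise_sd, size=(ny, nx))
        )
        frames[f] = noisy
        if f < n_frames - 1:
            t = f * dt
            vx, vy = flow.sample(x_um.ravel(), y_um.ravel(), t)
            # backward warp: new(x) = old(x - v dt)
            src_y = yy - vy.reshape(ny, nx) * dt / px
            src_x = xx - vx.reshape(ny, nx) * dt / px
            texture = ndimage.map_coordinates(
                texture, [src_y, src_x], order=3, mode="reflect"
            )
    np.clip(frames, 0, None, out=frames)
    return ImageStack(frames, pixel_size=px, frame_interval=dt, channel="cortex")
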