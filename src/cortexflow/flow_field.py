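"""Cortical flow-field estimation by two-pass FFT cross-correlation PIV.

The cortex channel is bleach-normalized, rolling-time-averaged and
high-pass filtered, then interrogated in two passes (64 px then 32 px
windows, the second pass offset by the first-pass estimate). Displacement
peaks are refined per axis with a 3-point Gaussian fit. Vectors failing a
velocity limit or a per-frame standard-deviation filter are replaced by
interpolation from their neighbours. The resulting field has a vector
every 16 px and supports bicubic spatial interpolation at arbitrary
positions (nearest frame in time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.fft import fft2, ifft2
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline, griddata

from .particle_sim import ImageStack

__all__ = ["PivParams", "FlowField", "piv", "sample_flow", "filter_vectors"]


@dataclass(frozen=True)
class PivParams:
    """PIV interrogation and post-filter settings (pixel/frame units)."""

    pass_windows: tuple[int, ...] = (64, 32)
    grid_spacing: int = 16
    highpass_size: float = 10.0
    velocity_limit: float = 0.3   # px/frame; vectors faster than this are outliers
    sd_filter: float = 5.0        # per-frame SD threshold
    time_average: int = 2         # rolling average window, frames

    def __post_init__(self) -> None:
        w = self.pass_windows
        if any(b >= a for a, b in zip(w, w[1:])) or any(x & (x - 1) for x in w):
            raise ValueError("pass_windows must be decreasing powers of two")
        if self.velocity_limit <= 0 or self.sd_filter <= 0:
            raise ValueError("velocity_limit and sd_filter must be positive")
        if self.grid_spacing <= 0 or self.time_average < 1:
            raise ValueError("invalid grid spacing or time average")


@dataclass
class FlowField:
    """Space-time grid of 2D velocity vectors with interpolating lookup.

    ``vx``/``vy`` are (t, ny, nx) arrays in µm/s on the (``grid_y`` ×
    ``grid_x``) µm grid at sample times ``times`` (s). ``valid`` marks
    vectors measured directly (False = filled by interpolation).
    """

    times: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: Optional[np.ndarray] = None
    interpolation_order: int = 3

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.ndim == 2:
            self.vx = self.vx[None]
            self.vy = self.vy[None]
        if not (np.isfinite(self.vx).all() and np.isfinite(self.vy).all()):
            raise ValueError("flow field contains non-finite vectors")
        if self.valid is None:
            self.valid = np.ones(self.vx.shape, dtype=bool)

    @classmethod
    def uniform(cls, vx: float, vy: float, extent: tuple[float, float] = (60.0, 60.0),
                spacing: float = 2.0, times: Sequence[float] = (0.0,)) -> "FlowField":
        gx = np.arange(0, extent[0] + spacing / 2, spacing)
        gy = np.arange(0, extent[1] + spacing / 2, spacing)
        shape = (len(times), len(gy), len(gx))
        return cls(np.asarray(times, dtype=float), gx, gy,
                   np.full(shape, float(vx)), np.full(shape, float(vy)))

    @classmethod
    def from_profile(cls, profile, extent: tuple[float, float] = (60.0, 60.0),
                     spacing: float = 1.0, times: Sequence[float] = (0.0,)) -> "FlowField":
        """Build a field whose vx varies with x as ``profile(x)`` and vy = 0."""
        gx = np.arange(0, extent[0] + spacing / 2, spacing)
        gy = np.arange(0, extent[1] + spacing / 2, spacing)
        vx = np.tile(profile(gx)[None, :], (len(gy), 1))
        vx = np.repeat(vx[None], len(times), axis=0)
        return cls(np.asarray(times, dtype=float), gx, gy, vx, np.zeros_like(vx))

    def _frame_index(self, t: float) -> int:
        # queries within one inter-frame spacing beyond the ends clamp to
        # the nearest frame (PIV times are frame-pair midpoints, so the
        # movie start/end fall half a frame outside the vector times)
        if len(self.times) > 1:
            tol = float(np.median(np.diff(self.times)))
            if t < self.times[0] - tol or t > self.times[-1] + tol:
                raise ValueError(f"time {t} outside flow field range "
                                 f"[{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - t)))

    def sample(self, x, y, t: float):
        """Bicubic vector lookup at positions (µm) and time t (s).

        Positions outside the grid hull are clamped to the nearest edge.
        """
        i = self._frame_index(t)
        x = np.clip(np.atleast_1d(np.asarray(x, dtype=float)),
                    self.grid_x[0], self.grid_x[-1])
        y = np.clip(np.atleast_1d(np.asarray(y, dtype=float)),
                    self.grid_y[0], self.grid_y[-1])
        k = min(self.interpolation_order, len(self.grid_x) - 1, len(self.grid_y) - 1)
        sx = RectBivariateSpline(self.grid_y, self.grid_x, self.vx[i], kx=k, ky=k)
        sy = RectBivariateSpline(self.grid_y, self.grid_x, self.vy[i], kx=k, ky=k)
        return sx(y, x, grid=False), sy(y, x, grid=False)

    def to_csv(self, path) -> None:
        tt, yy, xx = np.meshgrid(self.times, self.grid_y, self.grid_x, indexing="ij")
        pd.DataFrame({
            "t_s": tt.ravel(), "grid_x_um": xx.ravel(), "grid_y_um": yy.ravel(),
            "vx_um_s": self.vx.ravel(), "vy_um_s": self.vy.ravel(),
            "valid": self.valid.ravel().astype(int),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FlowField":
        df = pd.read_csv(path)
        times = np.unique(df["t_s"])
        gx = np.unique(df["grid_x_um"])
        gy = np.unique(df["grid_y_um"])
        shape = (len(times), len(gy), len(gx))
        df = df.sort_values(["t_s", "grid_y_um", "grid_x_um"], kind="stable")
        return cls(times, gx, gy,
                   df["vx_um_s"].to_numpy().reshape(shape),
                   df["vy_um_s"].to_numpy().reshape(shape),
                   df["valid"].to_numpy().reshape(shape).astype(bool))


def sample_flow(flow: FlowField, x, y, t: float):
    """Module-level alias for :meth:`FlowField.sample`."""
    return flow.sample(x, y, t)


def _xcorr_peak(a: np.ndarray, b: np.ndarray) -> Optional[tuple[float, float]]:
    """Displacement of window b relative to a from the FFT cross-correlation
    peak, with per-axis 3-point Gaussian subpixel refinement.

    Returns None for degenerate (flat) windows.
    """
    a = a - a.mean()
    b = b - b.mean()
    if a.std() < 1e-12 or b.std() < 1e-12:
        return None
    # zero-pad to twice the window so the correlation is linear, not
    # circular, and divide out the triangular overlap taper — both the
    # wrap-around and the taper bias broad peaks toward zero lag
    ny, nx = a.shape
    shape = (2 * ny, 2 * nx)
    corr = np.real(ifft2(fft2(b, shape) * np.conj(fft2(a, shape))))
    corr = np.fft.fftshift(corr)
    cy, cx = corr.shape[0] // 2, corr.shape[1] // 2
    lag_y = np.arange(corr.shape[0]) - cy
    lag_x = np.arange(corr.shape[1]) - cx
    overlap = np.outer(np.maximum(ny - np.abs(lag_y), 1),
                       np.maximum(nx - np.abs(lag_x), 1))
    corr = corr * (ny * nx) / overlap
    # search only within half a window; larger shifts are unreliable
    mask = (np.abs(lag_y)[:, None] > ny // 2) | (np.abs(lag_x)[None, :] > nx // 2)
    corr[mask] = -np.inf
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)

    def subpix(cm, c0, cp):
        # 3-point Gaussian fit needs a positive peak triplet; fall back to a
        # parabolic fit otherwise
        if not (np.isfinite(cm) and np.isfinite(cp)):
            return 0.0
        if c0 > 0 and cm > 0 and cp > 0 and c0 >= max(cm, cp):
            cm, c0, cp = np.log([cm, c0, cp])
        denom = cm - 2 * c0 + cp
        return 0.0 if denom == 0 else 0.5 * (cm - cp) / denom

    if 0 < iy < corr.shape[0] - 1:
        dy = iy - cy + subpix(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    else:
        dy = float(iy - cy)
    if 0 < ix < corr.shape[1] - 1:
        dx = ix - cx + subpix(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    else:
        dx = float(ix - cx)
    return dx, dy


def _preprocess(stack: ImageStack, params: PivParams) -> np.ndarray:
    frames = stack.frames.astype(float)
    # bleach correction: rescale every frame to the mean intensity of the first
    means = frames.mean(axis=(1, 2))
    frames = frames * (means[0] / means)[:, None, None]
    if params.time_average > 1 and frames.shape[0] >= params.time_average:
        kernel = np.ones(params.time_average) / params.time_average
        frames = ndimage.convolve1d(frames, kernel, axis=0, mode="nearest")
    if params.highpass_size > 0:
        frames = frames - ndimage.gaussian_filter(
            frames, (0, params.highpass_size, params.highpass_size))
    return frames


def _window(img: np.ndarray, cy: int, cx: int, half: int) -> Optional[np.ndarray]:
    y0, y1 = cy - half, cy + half
    x0, x1 = cx - half, cx + half
    if y0 < 0 or x0 < 0 or y1 > img.shape[0] or x1 > img.shape[1]:
        return None
    return img[y0:y1, x0:x1]


def filter_vectors(u: np.ndarray, v: np.ndarray, params: PivParams):
    """Apply the velocity-limit then SD filter; fill outliers by interpolation.

    Operates on one frame's (ny, nx) px/frame components. Returns filtered
    components plus the validity mask (False where replaced).
    """
    valid = np.isfinite(u) & np.isfinite(v)
    speed = np.hypot(np.where(valid, u, 0), np.where(valid, v, 0))
    valid &= speed <= params.velocity_limit
    for comp in (u, v):
        vals = comp[valid]
        if vals.size:
            m, s = vals.mean(), vals.std()
            if s > 0:
                valid &= np.abs(np.where(np.isfinite(comp), comp, m) - m) <= params.sd_filter * s
    if not valid.any():
        raise ValueError("all PIV vectors invalid in frame")
    if not valid.all():
        yy, xx = np.mgrid[0:u.shape[0], 0:u.shape[1]]
        pts = np.column_stack([yy[valid], xx[valid]])
        bad = np.column_stack([yy[~valid], xx[~valid]])
        for comp in (u, v):
            fill = griddata(pts, comp[valid], bad, method="linear")
            nn = griddata(pts, comp[valid], bad, method="nearest")
            fill = np.where(np.isfinite(fill), fill, nn)
            comp[~valid] = fill
    return u, v, valid


def piv(stack: ImageStack, params: PivParams = PivParams()) -> FlowField:
    """Estimate the flow field of an image stack by two-pass FFT PIV."""
    if stack.n_frames < 2:
        raise ValueError("PIV requires at least 2 frames")
    ny_px, nx_px = stack.frames.shape[1:]
    if min(ny_px, nx_px) < params.pass_windows[0]:
        raise ValueError("largest interrogation window does not fit in image")

    frames = _preprocess(stack, params)
    spacing = params.grid_spacing
    half_final = params.pass_windows[-1] // 2
    cx = np.arange(half_final, nx_px - half_final + 1, spacing)
    cy = np.arange(half_final, ny_px - half_final + 1, spacing)
    n_pairs = stack.n_frames - 1

    vx = np.empty((n_pairs, len(cy), len(cx)))
    vy = np.empty((n_pairs, len(cy), len(cx)))
    valid = np.empty((n_pairs, len(cy), len(cx)), dtype=bool)

    for f in range(n_pairs):
        a, b = frames[f], frames[f + 1]
        # pass 1: coarse integer estimate on a 64-px grid
        half1 = params.pass_windows[0] // 2
        c1x = np.arange(half1, nx_px - half1 + 1, half1)
        c1y = np.arange(half1, ny_px - half1 + 1, half1)
        u1 = np.zeros((len(c1y), len(c1x)))
        v1 = np.zeros((len(c1y), len(c1x)))
        for j, yc in enumerate(c1y):
            for i, xc in enumerate(c1x):
                wa = _window(a, yc, xc, half1)
                wb = _window(b, yc, xc, half1)
                if wa is None or wb is None:
                    continue
                pk = _xcorr_peak(wa, wb)
                if pk is not None:
                    u1[j, i], v1[j, i] = pk
        # interpolate pass-1 offsets to the final grid and round to integers
        if len(c1x) > 1 and len(c1y) > 1:
            ky = kx = min(1, len(c1y) - 1)
            su = RectBivariateSpline(c1y, c1x, u1, kx=1, ky=1)
            sv = RectBivariateSpline(c1y, c1x, v1, kx=1, ky=1)
            off_u = np.rint(su(cy, cx)).astype(int)
            off_v = np.rint(sv(cy, cx)).astype(int)
        else:
            off_u = np.full((len(cy), len(cx)), int(round(u1.mean())))
            off_v = np.full((len(cy), len(cx)), int(round(v1.mean())))

        u = np.full((len(cy), len(cx)), np.nan)
        v = np.full((len(cy), len(cx)), np.nan)
        for j, yc in enumerate(cy):
            for i, xc in enumerate(cx):
                du, dv = off_u[j, i], off_v[j, i]
                wa = _window(a, yc, xc, half_final)
                wb = _window(b, yc + dv, xc + du, half_final)
                if wb is None:
                    wb = _window(b, yc, xc, half_final)
                    du = dv = 0
                if wa is None or wb is None:
                    continue
                pk = _xcorr_peak(wa, wb)
                if pk is not None:
                    u[j, i] = pk[0] + du
                    v[j, i] = pk[1] + dv
        try:
            u, v, ok = filter_vectors(u, v, params)
        except ValueError as err:
            raise ValueError(f"frame {f}: {err}") from err
        vx[f], vy[f], valid[f] = u, v, ok

    scale = stack.pixel_size / stack.frame_interval
    times = (np.arange(n_pairs) + 0.5) * stack.frame_interval
    return FlowField(
        times=times,
        grid_x=(cx + 0.5) * stack.pixel_size,
        grid_y=(cy + 0.5) * stack.pixel_size,
        vx=vx * scale,
        vy=vy * scale,
        valid=valid,
    )
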