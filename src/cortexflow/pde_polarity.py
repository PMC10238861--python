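"""1D advection–diffusion–membrane-exchange model of polarity establishment.

A single membrane species A(x, t) on a 1D membrane of length L (x measured
from the anterior pole) obeys

    ∂A/∂t = D ∂²A/∂x² + ∂(vA)/∂x + k_on·A_cyt − k_off·A,
    A_cyt  = ρ_A − ψ·Ā,

where the uniform cytoplasmic pool A_cyt closes mass conservation through
the surface:volume ratio ψ and total amount ρ_A. The cortical flow
velocity v(x) is an experimentally fitted anterior-directed profile,
active during a flow phase (default 500 s, the polarity establishment
phase) and zero afterwards (maintenance phase). The +∂x(vA) sign means
positive v transports membrane mass toward the anterior pole at x = 0.

Spatially the equation is discretised as a conservative finite-volume
scheme (central face interpolation with an upwind fallback when negativity
appears); time integration is adaptive (explicit Runge–Kutta, switching to
LSODA when the diffusive stability limit would make explicit stepping
impractical). A two-species extension models membranes binding as a
mixture of fast- and slow-dissociating states sharing one cytoplasmic
pool.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "PdeParams",
    "TwoStateParams",
    "PdeSolution",
    "SegregationMetrics",
    "flow_velocity",
    "solve_pde",
    "solve_two_state",
    "compute_metrics",
    "sweep",
    "asymmetry_index",
    "posterior_depletion",
]

#: constants of the experimentally fitted flow profile
FLOW_PROFILE_CONSTANTS = (74.0, 391.0, 1000.0, 100.0)


def flow_velocity(x, L: float = 60.0,
                  constants: tuple[float, float, float, float] = FLOW_PROFILE_CONSTANTS):
    """Anterior-directed cortical flow profile fitted to experiment (µm/s).

    v(x) = ((L−x)/c1)·exp(−(L−x)²/c2) − (x/c3)·exp(−x²/c4); it vanishes at
    both poles and peaks (≈0.115 µm/s) in the posterior half, matching
    observed cortical flow speeds of ~0.1 µm/s.
    """
    c1, c2, c3, c4 = constants
    x = np.asarray(x, dtype=float)
    return (L - x) / c1 * np.exp(-((L - x) ** 2) / c2) - x / c3 * np.exp(-(x**2) / c4)


@dataclass(frozen=True)
class PdeParams:
    """Model and solver parameters.

    Units: µm, s. ``k_on`` defaults to ``k_off`` (the equilibrium the
    experimental M:C ratios imply); ``rho_A`` and ``psi`` default to the
    measured zygote values 1.56 µm⁻³ and 0.174 µm⁻¹.
    """

    D: float = 0.1
    k_off: float = 0.005
    k_on: Optional[float] = None
    rho_A: float = 1.56
    psi: float = 0.174
    L: float = 60.0
    n_grid: int = 400
    t_flow: float = 500.0
    t_post: float = 1500.0
    flow_constants: tuple[float, float, float, float] = FLOW_PROFILE_CONSTANTS
    flow_amplitude: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    save_interval: float = 1.0
    scheme: str = "central"
    method: str = "auto"

    def __post_init__(self) -> None:
        if min(self.D, self.k_off, self.rho_A, self.psi, self.L) < 0:
            raise ValueError("rates, lengths and amounts must be non-negative")
        if self.k_off <= 0:
            raise ValueError("k_off must be positive")
        if self.n_grid < 10:
            raise ValueError("n_grid too small")
        if self.t_flow < 0 or self.t_post < 0:
            raise ValueError("phase durations must be non-negative")
        if self.scheme not in ("central", "upwind"):
            raise ValueError("scheme must be 'central' or 'upwind'")

    @property
    def kon(self) -> float:
        return self.k_off if self.k_on is None else self.k_on

    @property
    def uniform_equilibrium(self) -> float:
        """Fixed point of the exchange terms for a uniform profile.

        k_on·(ρ_A − ψA) = k_off·A ⇒ A* = k_on·ρ_A / (k_off + k_on·ψ);
        with k_on = k_off this is ρ_A / (1 + ψ).
        """
        return self.kon * self.rho_A / (self.k_off + self.kon * self.psi)

    def replace(self, **kw) -> "PdeParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TwoStateParams:
    """Two membrane states (fast/slow dissociation) sharing one cytoplasmic
    pool; ``fraction_fast`` of binding events enter the fast state. The
    total binding rate is the base parameter set's k_on."""

    base: PdeParams = field(default_factory=PdeParams)
    k_off_fast: float = 1.0
    k_off_slow: float = 1e-3
    fraction_fast: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_fast <= 1.0):
            raise ValueError("fraction_fast must be in [0, 1]")
        if not (self.k_off_fast >= self.k_off_slow > 0):
            raise ValueError("need k_off_fast >= k_off_slow > 0")


@dataclass
class PdeSolution:
    """Membrane concentration field(s) plus the cytoplasmic pool over time.

    ``A`` is (nt, nx); for the two-state solver ``A`` is the total membrane
    pool and ``species`` holds the fast/slow fields separately.
    """

    times: np.ndarray
    x: np.ndarray
    A: np.ndarray
    A_cyt: np.ndarray
    t_flow: float
    params: object
    species: Optional[dict] = None

    @property
    def mean_membrane(self) -> np.ndarray:
        return self.A.mean(axis=1)

    def profile_at(self, t: float) -> np.ndarray:
        return self.A[int(np.argmin(np.abs(self.times - t)))]

    def mass_closure_error(self) -> float:
        """Max relative violation of ψĀ + A_cyt = ρ_A over time."""
        p = self.params if isinstance(self.params, PdeParams) else self.params.base
        total = p.psi * self.mean_membrane + self.A_cyt
        return float(np.abs(total - p.rho_A).max() / p.rho_A)


def _advection_diffusion_rhs(params: PdeParams, flow_on: bool,
                             scheme: Optional[str] = None):
    """Conservative finite-volume RHS for one membrane species (exchange
    terms excluded); returns (rhs(A) -> dA, cell centers)."""
    n = params.n_grid
    dx = params.L / n
    xc = (np.arange(n) + 0.5) * dx
    xf = np.arange(1, n) * dx
    vf = (params.flow_amplitude * flow_velocity(xf, params.L, params.flow_constants)
          if flow_on else np.zeros(n - 1))
    scheme = scheme or params.scheme
    central = scheme == "central"

    def rhs(A: np.ndarray) -> np.ndarray:
        # flux F = -D dA/dx - v A; +∂x(vA) in the PDE means the advective
        # flux is -vA (anterior-directed for v > 0)
        Fd = -params.D * np.diff(A) / dx
        if central:
            Af = 0.5 * (A[:-1] + A[1:])
        else:
            Af = np.where(vf > 0, A[1:], A[:-1])  # donor cell for flux toward -x
        F = Fd - vf * Af
        dA = np.empty_like(A)
        dA[0] = -F[0] / dx
        dA[-1] = F[-1] / dx
        dA[1:-1] = -(F[1:] - F[:-1]) / dx
        return dA

    return rhs, xc


def _pick_method(params: PdeParams) -> str:
    if params.method != "auto":
        return params.method
    dx = params.L / params.n_grid
    horizon = params.t_flow + params.t_post
    explicit_steps = horizon * 2 * params.D / dx**2 if params.D > 0 else 0
    return "LSODA" if explicit_steps > 5e4 else "RK45"


def _integrate_phases(rhs_flow: Callable, rhs_post: Callable, y0: np.ndarray,
                      params: PdeParams) -> tuple[np.ndarray, np.ndarray]:
    method = _pick_method(params)
    dt = params.save_interval
    t1 = np.arange(0.0, params.t_flow + dt / 2, dt)
    sols = []
    y_end = y0
    if params.t_flow > 0:
        s1 = solve_ivp(lambda t, y: rhs_flow(y), (0.0, params.t_flow), y0,
                       t_eval=t1, method=method, rtol=params.rtol, atol=params.atol)
        if not s1.success:
            raise RuntimeError(f"flow-phase integration failed: {s1.message}")
        sols.append((t1, s1.y.T))
        y_end = s1.y[:, -1]
    else:
        sols.append((np.array([0.0]), y0[None, :]))
    if params.t_post > 0:
        t2 = np.arange(dt, params.t_post + dt / 2, dt)
        s2 = solve_ivp(lambda t, y: rhs_post(y), (0.0, params.t_post), y_end,
                       t_eval=t2, method=method, rtol=params.rtol, atol=params.atol)
        if not s2.success:
            raise RuntimeError(f"post-flow integration failed: {s2.message}")
        sols.append((params.t_flow + t2, s2.y.T))
    times = np.concatenate([t for t, _ in sols])
    Y = np.vstack([y for _, y in sols])
    return times, Y


def solve_pde(params: PdeParams) -> PdeSolution:
    """Integrate the single-species model over flow and post-flow phases.

    Starts from the uniform equilibrium, runs the printed flow profile for
    ``t_flow`` seconds, then sets v = 0 and relaxes for ``t_post`` seconds.
    Raises if the solution develops negative concentrations beyond
    tolerance (the central scheme automatically falls back to upwind
    if that happens).
    """
    for scheme in ((params.scheme, "upwind") if params.scheme == "central"
                   else (params.scheme,)):
        transport_flow, xc = _advection_diffusion_rhs(params, True, scheme)
        transport_post, _ = _advection_diffusion_rhs(params, False, scheme)
        kon, koff = params.kon, params.k_off

        def make(transport):
            def rhs(A):
                Acyt = params.rho_A - params.psi * A.mean()
                return transport(A) + kon * Acyt - koff * A
            return rhs

        times, Y = _integrate_phases(make(transport_flow), make(transport_post),
                                     np.full(params.n_grid, params.uniform_equilibrium),
                                     params)
        neg = -Y.min() if Y.min() < 0 else 0.0
        if neg <= 1e-8 * params.rho_A:
            break
    if neg > 1e-8 * params.rho_A:
        raise RuntimeError(
            f"negative concentrations (min {Y.min():.3e}) under both face schemes")
    Y = np.clip(Y, 0.0, None)
    A_cyt = params.rho_A - params.psi * Y.mean(axis=1)
    return PdeSolution(times=times, x=xc, A=Y, A_cyt=A_cyt,
                       t_flow=params.t_flow, params=params)


def solve_two_state(tparams: TwoStateParams) -> PdeSolution:
    """Two membrane species (fast/slow k_off) sharing one cytoplasmic pool.

    Binding flux k_on·A_cyt is split fraction_fast : (1 − fraction_fast)
    between the species; both are advected and diffuse identically. The
    initial condition is the uniform two-species equilibrium. The returned
    solution's ``A`` is the total membrane pool; ``species`` carries the
    fast/slow fields and the fast membrane share over time.
    """
    p = tparams.base
    n = p.n_grid
    kon = p.kon
    f = tparams.fraction_fast
    kf, ks = tparams.k_off_fast, tparams.k_off_slow

    transport_flow, xc = _advection_diffusion_rhs(p, True)
    transport_post, _ = _advection_diffusion_rhs(p, False)

    def make(transport):
        def rhs(Y):
            Af, As = Y[:n], Y[n:]
            Acyt = p.rho_A - p.psi * (Af.mean() + As.mean())
            dAf = transport(Af) + f * kon * Acyt - kf * Af
            dAs = transport(As) + (1 - f) * kon * Acyt - ks * As
            return np.concatenate([dAf, dAs])
        return rhs

    # uniform equilibrium: A_f* = f k_on A_cyt*/k_f, A_s* = (1-f) k_on A_cyt*/k_s
    occ = kon * (f / kf + (1 - f) / ks)
    Acyt0 = p.rho_A / (1 + p.psi * occ)
    y0 = np.concatenate([np.full(n, f * kon * Acyt0 / kf),
                         np.full(n, (1 - f) * kon * Acyt0 / ks)])
    times, Y = _integrate_phases(make(transport_flow), make(transport_post), y0, p)
    if Y.min() < -1e-8 * p.rho_A:
        raise RuntimeError(f"negative concentrations (min {Y.min():.3e})")
    Y = np.clip(Y, 0.0, None)
    Af, As = Y[:, :n], Y[:, n:]
    A = Af + As
    A_cyt = p.rho_A - p.psi * A.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fast_share = np.where(A.mean(axis=1) > 0,
                              Af.mean(axis=1) / A.mean(axis=1), np.nan)
    return PdeSolution(times=times, x=xc, A=A, A_cyt=A_cyt, t_flow=p.t_flow,
                       params=tparams,
                       species={"fast": Af, "slow": As,
                               "fast_membrane_share": fast_share})


# ---------------------------------------------------------------------------
# segregation metrics

def pole_means(profile: np.ndarray, pole_fraction: float = 0.3) -> tuple[float, float]:
    """Anterior/posterior pole means of a 1D anterior→posterior profile."""
    profile = np.asarray(profile, dtype=float)
    m = max(int(round(pole_fraction * len(profile))), 1)
    return float(profile[:m].mean()), float(profile[-m:].mean())


def asymmetry_index(anterior: float, posterior: float,
                    convention: str = "half") -> float:
    """ASI from pole-mean concentrations.

    ``convention='half'`` (default): (A−P)/(2(A+P)), maximum 0.5 at complete
    posterior clearance. ``convention='full'``: (A−P)/(A+P), maximum 1.
    """
    denom = anterior + posterior
    if denom == 0:
        return 0.0
    asi = (anterior - posterior) / denom
    return asi / 2 if convention == "half" else asi


def posterior_depletion(posterior: float, mean_intensity: float,
                        convention: str = "cleared") -> float:
    """Posterior depletion from the posterior pole mean and overall mean.

    ``convention='cleared'`` (default): 1 − P/<I>, maximum 1 at complete
    clearance. ``convention='ratio'``: the raw ratio P/<I>.
    """
    if mean_intensity == 0:
        return 0.0
    ratio = posterior / mean_intensity
    return 1 - ratio if convention == "cleared" else ratio


@dataclass
class SegregationMetrics:
    """Time courses and summary statistics of flow-induced segregation."""

    times: np.ndarray
    asi: np.ndarray
    depletion: np.ndarray
    peak_asi: float                 # at the end of the flow phase
    peak_depletion: float
    max_asi: float                  # max over all times (coincides with peak
    max_depletion: float            # for monotone growth during flow)
    asi_post300: float              # 300 s after flow ceases
    depletion_post300: float
    t_half_asi: float               # first crossing of half the end-of-flow value
    t_half_depletion: float
    t_half_asi_expfit: float        # exponential-decay cross-check (ln2 · τ_fit)
    t_half_depletion_expfit: float
    anterior_pole: float            # pole means at end of flow
    posterior_pole: float
    convention: str = "half/cleared"


def _first_half_crossing(t: np.ndarray, y: np.ndarray, y0: float) -> float:
    """First time y falls to y0/2, linearly interpolated; inf if never."""
    half = y0 / 2
    below = np.nonzero(y <= half)[0]
    if not len(below) or y0 <= 0:
        return float("inf")
    i = below[0]
    if i == 0:
        return float(t[0])
    t0, t1_, ya, yb = t[i - 1], t[i], y[i - 1], y[i]
    if ya == yb:
        return float(t1_)
    return float(t0 + (ya - half) / (ya - yb) * (t1_ - t0))


def _exp_halftime(t: np.ndarray, y: np.ndarray) -> float:
    """Half-time from an exponential decay fit y = y0·exp(−t/τ)."""
    if len(t) < 3 or y[0] <= 0:
        return float("inf")
    try:
        popt, _ = curve_fit(lambda tt, y0, tau: y0 * np.exp(-tt / tau),
                            t - t[0], y, p0=(y[0], max((t[-1] - t[0]) / 3, 1.0)),
                            maxfev=5000)
    except RuntimeError:
        return float("inf")
    return float(np.log(2) * popt[1])


def compute_metrics(sol: PdeSolution, pole_fraction: float = 0.3,
                    asi_convention: str = "half",
                    depletion_convention: str = "cleared") -> SegregationMetrics:
    """Segregation metrics of a PDE solution.

    Pole means are taken over the anterior-/posterior-most
    ``pole_fraction`` of the domain. Peak values are read at the end of the
    flow phase; decay half-times are the first post-flow crossing of half
    the end-of-flow value (an exponential-fit estimate is reported as a
    cross-check). A metric that never reaches half its end-of-flow value
    within the simulated window is reported as inf (i.e. > t_post).
    """
    n = sol.A.shape[1]
    m = max(int(round(pole_fraction * n)), 1)
    ant = sol.A[:, :m].mean(axis=1)
    post = sol.A[:, -m:].mean(axis=1)
    mean_I = sol.A.mean(axis=1)

    asi = np.array([asymmetry_index(a, p, asi_convention)
                    for a, p in zip(ant, post)])
    dep = np.array([posterior_depletion(p, mi, depletion_convention)
                    for p, mi in zip(post, mean_I)])

    i_end = int(np.argmin(np.abs(sol.times - sol.t_flow)))
    peak_asi = float(asi[i_end])
    peak_dep = float(dep[i_end])
    i_300 = int(np.argmin(np.abs(sol.times - (sol.t_flow + 300.0))))

    post_mask = sol.times >= sol.t_flow
    tp, ap, dp = sol.times[post_mask], asi[post_mask], dep[post_mask]
    rel = tp - sol.t_flow
    return SegregationMetrics(
        times=sol.times, asi=asi, depletion=dep,
        peak_asi=peak_asi, peak_depletion=peak_dep,
        max_asi=float(asi.max()), max_depletion=float(dep.max()),
        asi_post300=float(asi[i_300]), depletion_post300=float(dep[i_300]),
        t_half_asi=_first_half_crossing(rel, ap, peak_asi),
        t_half_depletion=_first_half_crossing(rel, dp, peak_dep),
        t_half_asi_expfit=_exp_halftime(rel, ap),
        t_half_depletion_expfit=_exp_halftime(rel, dp),
        anterior_pole=float(ant[i_end]), posterior_pole=float(post[i_end]),
        convention=f"{asi_convention}/{depletion_convention}",
    )


def sweep(D_values: Sequence[float], k_off_values: Sequence[float],
          params: Optional[PdeParams] = None, **metric_kw) -> pd.DataFrame:
    """Phase-diagram sweep: solve + score every (D, k_off) with k_on = k_off.

    Returns a tidy frame of the four phase-diagram surfaces (peak ASI, peak
    depletion and both decay half-times). Individual cell failures are
    recorded in the ``error`` column and do not stop the sweep.
    """
    base = params or PdeParams()
    rows = []
    for D in D_values:
        for koff in k_off_values:
            row = {"D_um2_s": D, "k_off_s": koff, "error": ""}
            try:
                sol = solve_pde(base.replace(D=D, k_off=koff, k_on=None))
                m = compute_metrics(sol, **metric_kw)
                row.update(peak_asi=m.peak_asi, peak_depletion=m.peak_depletion,
                           t_half_asi=m.t_half_asi, t_half_depletion=m.t_half_depletion,
                           asi_post300=m.asi_post300,
                           depletion_post300=m.depletion_post300)
            except (RuntimeError, ValueError) as err:
                row["error"] = str(err)
            rows.append(row)
    return pd.DataFrame(rows)
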