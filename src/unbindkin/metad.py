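"""Well-tempered and infrequent metadynamics on model landscapes.

Bias is a sum of Gaussian hills deposited along the reaction coordinate with
well-tempered height decay h = h0 exp(-V/((gamma-1) kBT)).  Infrequent
release runs recover physical time through the acceleration factor
alpha = <exp(V(r,t)/kBT)> (running average over the biased trajectory up to
the first committed release), t_unbiased = t_biased * alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dynamics
from .dynamics import LangevinParams, Trajectory, IntegrationError, _EMPTY
from .kinetics import ReleaseTimeEnsemble, InsufficientDataError


@dataclass
class WellTemperedParams:
    """Well-tempered bias deposition parameters.

    Defaults mirror common rare-event practice for this problem class:
    0.60 kcal/mol initial height, hills every 50 ps, bias factor 10.  The
    hill width is set to the scale of the model wells (0.25 Å) rather than
    the much narrower widths appropriate to atomistic path CVs.
    """

    height0: float = 0.60  # kcal/mol
    sigmas: tuple = (0.25,)  # Å per biased CV
    stride: float = 50.0  # ps between depositions
    bias_factor: float = 10.0  # gamma
    temperature: float = 300.0  # K

    def __post_init__(self):
        if self.height0 <= 0:
            raise ValueError("height0 must be positive")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be positive")
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")

    @property
    def kbt(self) -> float:
        from .units import KB_KCAL
        return KB_KCAL * self.temperature


@dataclass
class Hill:
    time: float  # ps
    center: tuple  # per CV, Å
    width: tuple  # per CV, Å
    height: float  # deposited (already well-tempered) height, kcal/mol


@dataclass
class BiasState:
    """Time-ordered record of deposited Gaussians defining V(s, t)."""

    gaussians: list = field(default_factory=list)
    params: WellTemperedParams = field(default_factory=WellTemperedParams)

    def __len__(self):
        return len(self.gaussians)

    def append(self, hill: Hill):
        if self.gaussians and hill.time <= self.gaussians[-1].time:
            raise ValueError("hill times must be strictly increasing")
        if hill.height <= 0:
            raise ValueError("hill heights must be positive")
        self.gaussians.append(hill)

    def arrays(self):
        """(times, centers (n, d), widths (n, d), heights) as arrays."""
        n = len(self.gaussians)
        if n == 0:
            z = np.empty((0,))
            return z, np.empty((0, 1)), np.empty((0, 1)), z
        t = np.array([g.time for g in self.gaussians])
        c = np.array([g.center for g in self.gaussians], dtype=float)
        w = np.array([g.width for g in self.gaussians], dtype=float)
        h = np.array([g.height for g in self.gaussians])
        return t, np.atleast_2d(c), np.atleast_2d(w), h


def bias_value(point, bias: BiasState, at_time: float,
               with_gradient: bool = False):
    """Total bias (kcal/mol) at `point` from hills deposited at times
    <= at_time; optionally the gradient wrt the CVs."""
    if at_time < 0:
        raise ValueError("at_time must be non-negative")
    point = np.atleast_1d(np.asarray(point, float))
    t, c, w, h = bias.arrays()
    grad = np.zeros_like(point)
    if len(t) == 0:
        return (0.0, grad) if with_gradient else 0.0
    m = t <= at_time
    if not m.any():
        return (0.0, grad) if with_gradient else 0.0
    d = (point[None, :] - c[m]) / w[m]
    e = h[m] * np.exp(-0.5 * np.sum(d * d, axis=1))
    v = float(e.sum())
    if not with_gradient:
        return v
    grad = -np.sum(e[:, None] * d / w[m], axis=0)
    return v, grad


def deposit(bias: BiasState, current_point, t: float) -> BiasState:
    """Append a well-tempered hill at `current_point` and time `t` (ps)."""
    point = np.atleast_1d(np.asarray(current_point, float))
    wt = bias.params
    v_here = bias_value(point, bias, t)
    h = wt.height0 * np.exp(-v_here / ((wt.bias_factor - 1.0) * wt.kbt))
    sig = wt.sigmas if len(wt.sigmas) == point.size else tuple(
        [wt.sigmas[0]] * point.size)
    bias.append(Hill(time=t, center=tuple(point), width=tuple(sig), height=h))
    return bias


def acceleration_factor(v_series, kbt: float) -> np.ndarray:
    """Running acceleration factor alpha_k = (1/k) sum_{i<=k} e^{V_i/kBT}.

    Computed in log space so that large bias values cannot overflow the
    accumulator; returns the full running series (last element is the
    current alpha).
    """
    v = np.asarray(v_series, dtype=float)
    if v.size == 0:
        raise ValueError("empty bias series")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite bias values")
    a = v / kbt
    log_cum = np.logaddexp.accumulate(a)
    log_alpha = log_cum - np.log(np.arange(1, v.size + 1))
    return np.exp(log_alpha)


@dataclass
class ReleaseRun:
    """One infrequent-metadynamics release simulation."""

    trajectory: Trajectory
    bias_state: BiasState
    t_biased: float  # ns
    acceleration: float  # alpha at first committed crossing
    t_unbiased: float  # ns, = t_biased * alpha
    released: bool
    criterion: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def run_release(landscape, params: LangevinParams, wt: WellTemperedParams,
                release_cv=None, threshold: float = 22.0,
                commit_window: float = 100.0, max_time: float = 2.0e5,
                seed: int | None = None, rebind_floor: float | None = None,
                save_stride: int = 50) -> ReleaseRun:
    """Run one biased release simulation until the coordinate exceeds
    `threshold` (Å) and stays above the rebind floor for `commit_window` (ps),
    or until `max_time` (ps).

    Bias deposition pauses once the threshold is crossed; the time of the
    first committed crossing defines t_biased and the acceleration factor is
    the running average accumulated up to that crossing.
    """
    if landscape.dims != 1:
        raise ValueError("release runs are 1D (the d1-like coordinate)")
    if not (landscape.wall_lo < threshold <= landscape.wall_hi + 2.0):
        raise ValueError("threshold must lie inside the domain")
    if max_time <= wt.stride:
        raise ValueError("max_time must exceed the deposition stride")
    if seed is None:
        seed = params.seed
    if rebind_floor is None:
        rebind_floor = threshold - 4.0
    dt = params.timestep
    n_steps = int(max_time / dt)
    dep_stride = max(int(round(wt.stride / dt)), 1)
    commit_steps = max(int(round(commit_window / dt)), 1)
    sigma = float(wt.sigmas[0])

    grid_lo = landscape.wall_lo - 2.0
    grid_hi = landscape.wall_hi + 2.0
    grid_dx = min(sigma / 4.0, 0.05)
    ngrid = int((grid_hi - grid_lo) / grid_dx) + 2
    vgrid = np.zeros(ngrid)
    fgrid = np.zeros(ngrid)
    max_hills = n_steps // dep_stride + 1
    hills_t = np.zeros(max_hills)
    hills_c = np.zeros(max_hills)
    hills_h = np.zeros(max_hills)
    n_frames = max(n_steps // save_stride, 1)
    out_x = np.empty(n_frames)
    out_vb = np.empty(n_frames)

    amps, cens, wids = landscape.gaussian_arrays()
    res = dynamics._run_1d(
        float(landscape.default_start), 0.0, n_steps, dt, params.mass,
        params.friction, params.kbt, int(seed) & 0x7FFFFFFF,
        amps, cens, wids, landscape.wall_lo, landscape.k_wall,
        landscape.wall_hi, landscape.k_wall,
        1e30, -1.0,
        _EMPTY, _EMPTY, _EMPTY,
        int(save_stride),
        1, wt.height0, sigma, wt.bias_factor, dep_stride,
        grid_lo, grid_dx, vgrid, fgrid,
        hills_t, hills_c, hills_h,
        1, float(threshold), float(rebind_floor), commit_steps,
        0,
        out_x, out_vb)
    (status, err_step, n_saved, n_hills, released, cross_step, alpha_cross,
     sum_expv, steps_done, x_fin, v_fin) = res
    if status != 0:
        raise IntegrationError(err_step)

    bias = BiasState(params=wt)
    for i in range(n_hills):
        bias.append(Hill(time=hills_t[i], center=(hills_c[i],),
                         width=(sigma,), height=hills_h[i]))
    times = dt * save_stride * np.arange(1, n_saved + 1)
    traj = Trajectory(times=times, coords=out_x[:n_saved].copy(), seed=seed)

    released = bool(released)
    if released:
        t_biased = cross_step * dt / 1000.0  # ns
        alpha = float(alpha_cross)
    else:
        t_biased = steps_done * dt / 1000.0
        alpha = float(sum_expv / max(steps_done, 1))
    t_unbiased = t_biased * alpha

    barrier_pos = [x for (lab, x, *_rest) in landscape.feature_table
                   if lab.startswith("TS")]
    near = sum(1 for i in range(n_hills)
               if any(abs(hills_c[i] - b) < 2 * sigma for b in barrier_pos))
    diagnostics = {"hills_near_barrier": int(near), "n_hills": int(n_hills),
                   "bias_energy_series": out_vb[:n_saved].copy()}
    if near > 0 and released:
        warnings.warn(
            f"{near} hills deposited within 2 sigma of a barrier top; "
            "the infrequent-metadynamics time rescaling may be degraded",
            RuntimeWarning, stacklevel=2)
    criterion = {"threshold": threshold, "rebind_floor": rebind_floor,
                 "commit_window_ps": commit_window, "max_time_ps": max_time}
    return ReleaseRun(trajectory=traj, bias_state=bias, t_biased=t_biased,
                      acceleration=alpha, t_unbiased=t_unbiased,
                      released=released, criterion=criterion,
                      diagnostics=diagnostics)


def run_metadynamics(landscape, params: LangevinParams,
                     wt: WellTemperedParams, total_time: float,
                     restraints=None, seed: int | None = None,
                     save_stride: int = 50, x0: float | None = None
                     ) -> tuple[Trajectory, BiasState]:
    """Plain well-tempered metadynamics run (no release detection).

    Used for free-energy estimation: the system recrosses between bound and
    unbound basins while the bias converges.  `restraints` may hold one
    upper-wall object confining the unbound excursion.
    """
    if landscape.dims != 1:
        raise ValueError("the fast engine is 1D")
    if seed is None:
        seed = params.seed
    dt = params.timestep
    n_steps = int(total_time / dt)
    dep_stride = max(int(round(wt.stride / dt)), 1)
    sigma = float(wt.sigmas[0])
    rest_at, rest_k = 1e30, -1.0
    if restraints:
        if len(restraints) != 1:
            raise ValueError("at most one upper-wall restraint in the fast path")
        rest_at, rest_k = float(restraints[0].at), float(restraints[0].k)

    grid_lo = landscape.wall_lo - 2.0
    grid_hi = landscape.wall_hi + 2.0
    grid_dx = min(sigma / 4.0, 0.05)
    ngrid = int((grid_hi - grid_lo) / grid_dx) + 2
    vgrid = np.zeros(ngrid)
    fgrid = np.zeros(ngrid)
    max_hills = n_steps // dep_stride + 1
    hills_t = np.zeros(max_hills)
    hills_c = np.zeros(max_hills)
    hills_h = np.zeros(max_hills)
    n_frames = max(n_steps // save_stride, 1)
    out_x = np.empty(n_frames)
    out_vb = np.empty(n_frames)
    amps, cens, wids = landscape.gaussian_arrays()
    if x0 is None:
        x0 = landscape.default_start
    res = dynamics._run_1d(
        float(x0), 0.0, n_steps, dt, params.mass,
        params.friction, params.kbt, int(seed) & 0x7FFFFFFF,
        amps, cens, wids, landscape.wall_lo, landscape.k_wall,
        landscape.wall_hi, landscape.k_wall,
        rest_at, rest_k,
        _EMPTY, _EMPTY, _EMPTY,
        int(save_stride),
        1, wt.height0, sigma, wt.bias_factor, dep_stride,
        grid_lo, grid_dx, vgrid, fgrid,
        hills_t, hills_c, hills_h,
        0, 0.0, 0.0, 0,
        0,
        out_x, out_vb)
    status, err_step, n_saved, n_hills = res[0], res[1], res[2], res[3]
    if status != 0:
        raise IntegrationError(err_step)
    bias = BiasState(params=wt)
    for i in range(n_hills):
        bias.append(Hill(time=hills_t[i], center=(hills_c[i],),
                         width=(sigma,), height=hills_h[i]))
    times = dt * save_stride * np.arange(1, n_saved + 1)
    return (Trajectory(times=times, coords=out_x[:n_saved].copy(), seed=seed),
            bias)


def ensemble_release(landscape, params: LangevinParams,
                     wt: WellTemperedParams, n_runs: int = 25,
                     seeds=None, **release_kwargs) -> ReleaseTimeEnsemble:
    """Collect unbiased release times from `n_runs` independent biased runs.

    Runs that never release within max_time are excluded from the fit and
    counted in the ensemble metadata.
    """
    if n_runs < 2:
        raise InsufficientDataError("need at least 2 release runs")
    if seeds is None:
        rng = np.random.default_rng(params.seed)
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("seeds length must equal n_runs")
    times = []
    excluded = 0
    for s in seeds:
        run = run_release(landscape, params, wt, seed=s, **release_kwargs)
        if run.released:
            times.append(run.t_unbiased)
        else:
            excluded += 1
    if len(times) < 2:
        raise InsufficientDataError(
            f"only {len(times)} of {n_runs} runs released")
    return ReleaseTimeEnsemble(times=np.array(times), seeds=list(seeds),
                               excluded=excluded)
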