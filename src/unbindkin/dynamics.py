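"""Langevin dynamics on model landscapes.

The workhorse is a single compiled 1D kernel that integrates underdamped
(BAOAB splitting) or overdamped (Euler–Maruyama) Langevin dynamics with
optional harmonic walls, a frozen external bias, and on-the-fly well-tempered
metadynamics with release detection.  The metadynamics bias is accumulated on
a grid so the per-step cost is independent of the number of deposited hills.

A slower pure-Python integrator handles arbitrary dimensionality and force
callables (used for 2D landscapes with funnel restraints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .units import KB_KCAL, KCAL_PER_AMU_A2_PS2


class IntegrationError(RuntimeError):
    """Raised when a non-finite force or coordinate is encountered."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite force/coordinate at step {step}")


@dataclass
class LangevinParams:
    """Parameters of the effective-coordinate Langevin model.

    The friction sets the configurational diffusion coefficient
    D = kBT / (m * gamma) and is a free parameter of the synthetic model;
    the default (20 ps^-1) puts barrier-crossing kinetics in the overdamped
    regime where 1D mean-first-passage-time theory applies.
    """

    timestep: float = 0.02  # ps
    friction: float = 20.0  # ps^-1
    mass: float = 40.0  # amu, effective mass of the d1 coordinate
    temperature: float = 300.0  # K
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.mass <= 0 or self.temperature < 0:
            raise ValueError("mass must be positive and temperature non-negative")

    @property
    def kbt(self) -> float:
        """Thermal energy in kcal/mol."""
        return KB_KCAL * self.temperature

    @property
    def diffusion(self) -> float:
        """Overdamped configurational diffusion coefficient, Å²/ps."""
        return self.kbt / (self.mass * KCAL_PER_AMU_A2_PS2 * self.friction)


@dataclass
class Trajectory:
    """Uniform-stride CV time series from one simulation."""

    times: np.ndarray  # ps, strictly increasing, uniform stride
    coords: np.ndarray  # (n_frames,) or (n_frames, dims), Å
    cv_labels: tuple = ("d1",)
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.times) != len(self.coords):
            raise ValueError("times and coords must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.all(dt > 0) or not np.allclose(dt, dt[0], rtol=1e-8):
                raise ValueError("times must be strictly increasing with uniform stride")

    def __len__(self):
        return len(self.times)

    @property
    def stride(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


_EMPTY = np.empty(0, dtype=np.float64)


@njit(cache=True)
def _pot_1d(x, amps, cens, wids, wall_lo, k_lo, wall_hi, k_hi,
            rest_at, rest_k):
    u = 0.0
    for i in range(amps.size):
        d = (x - cens[i]) / wids[i]
        u += amps[i] * np.exp(-0.5 * d * d)
    if x < wall_lo:
        u += 0.5 * k_lo * (x - wall_lo) ** 2
    if x > wall_hi:
        u += 0.5 * k_hi * (x - wall_hi) ** 2
    if rest_k > 0.0 and x > rest_at:
        u += 0.5 * rest_k * (x - rest_at) ** 2
    return u


@njit(cache=True)
def _force_1d(x, amps, cens, wids, wall_lo, k_lo, wall_hi, k_hi,
              rest_at, rest_k):
    f = 0.0
    for i in range(amps.size):
        d = (x - cens[i]) / wids[i]
        f += amps[i] * np.exp(-0.5 * d * d) * d / wids[i]
    if x < wall_lo:
        f -= k_lo * (x - wall_lo)
    if x > wall_hi:
        f -= k_hi * (x - wall_hi)
    if rest_k > 0.0 and x > rest_at:
        f -= rest_k * (x - rest_at)
    return f


@njit(cache=True)
def _grid_interp(x, grid_lo, grid_dx, grid):
    n = grid.size
    if n == 0:
        return 0.0
    u = (x - grid_lo) / grid_dx
    if u <= 0.0:
        return grid[0]
    if u >= n - 1:
        return grid[n - 1]
    i = int(u)
    frac = u - i
    return grid[i] * (1.0 - frac) + grid[i + 1] * frac


@njit(cache=True)
def _run_1d(x0, v0, n_steps, dt, mass, gamma, kbt_val, seed,
            amps, cens, wids, wall_lo, k_lo, wall_hi, k_hi,
            rest_at, rest_k,
            st_amps, st_cens, st_wids,
            save_stride,
            metad_on, h0, sigma, biasf, dep_stride,
            grid_lo, grid_dx, vgrid, fgrid,
            hills_t, hills_c, hills_h,
            release_on, threshold, floor, commit_steps,
            overdamped,
            out_x, out_vbias):
    np.random.seed(seed)
    c = KCAL_PER_AMU_A2_PS2
    x = x0
    v = v0
    a_fric = np.exp(-gamma * dt)
    sig_v = np.sqrt(kbt_val / (mass * c) * (1.0 - a_fric * a_fric))
    diff = kbt_val / (mass * c * gamma)
    sig_od = np.sqrt(2.0 * diff * dt)
    inv_sig2 = 1.0 / (sigma * sigma) if sigma > 0.0 else 0.0
    ngrid = vgrid.size

    sum_expv = 0.0
    n_saved = 0
    n_hills = 0
    pending = False
    pend_step = -1
    alpha_cross = 1.0
    released = 0
    first_cross = -1  # the first threshold crossing defines t_biased/alpha
    steps_done = 0

    for step in range(n_steps):
        f = _force_1d(x, amps, cens, wids, wall_lo, k_lo, wall_hi, k_hi,
                      rest_at, rest_k)
        f += _force_1d(x, st_amps, st_cens, st_wids, -1e30, 0.0, 1e30, 0.0,
                       0.0, -1.0)
        f += _grid_interp(x, grid_lo, grid_dx, fgrid)
        if not np.isfinite(f) or not np.isfinite(x):
            return (1, step, n_saved, n_hills, released, first_cross,
                    alpha_cross, sum_expv, steps_done, x, v)
        if overdamped:
            x = x + f / (mass * c * gamma) * dt + sig_od * np.random.normal()
        else:
            v += 0.5 * dt * f / (mass * c)
            x += 0.5 * dt * v
            v = a_fric * v + sig_v * np.random.normal()
            x += 0.5 * dt * v
            f2 = _force_1d(x, amps, cens, wids, wall_lo, k_lo, wall_hi, k_hi,
                           rest_at, rest_k)
            f2 += _force_1d(x, st_amps, st_cens, st_wids, -1e30, 0.0, 1e30,
                            0.0, 0.0, -1.0)
            f2 += _grid_interp(x, grid_lo, grid_dx, fgrid)
            v += 0.5 * dt * f2 / (mass * c)
        steps_done = step + 1
        t = steps_done * dt

        vbias = _grid_interp(x, grid_lo, grid_dx, vgrid)
        vbias += _pot_1d(x, st_amps, st_cens, st_wids, -1e30, 0.0, 1e30, 0.0,
                         0.0, -1.0)
        arg = vbias / kbt_val
        if arg > 700.0:
            arg = 700.0
        sum_expv += np.exp(arg)

        if release_on == 1:
            if first_cross < 0 and x > threshold:
                first_cross = steps_done
                alpha_cross = sum_expv / steps_done
            if not pending:
                if x > threshold:
                    pending = True
                    pend_step = steps_done
            else:
                if x < floor:
                    pending = False
                elif steps_done - pend_step >= commit_steps:
                    released = 1
        if (step + 1) % save_stride == 0 and n_saved < out_x.size:
            out_x[n_saved] = x
            out_vbias[n_saved] = vbias
            n_saved += 1
        if released == 1:
            break

        if (metad_on == 1 and first_cross < 0 and
                (step + 1) % dep_stride == 0 and n_hills < hills_t.size):
            vhere = _grid_interp(x, grid_lo, grid_dx, vgrid)
            h = h0 * np.exp(-vhere / ((biasf - 1.0) * kbt_val))
            hills_t[n_hills] = t
            hills_c[n_hills] = x
            hills_h[n_hills] = h
            n_hills += 1
            lo_i = int((x - 6.0 * sigma - grid_lo) / grid_dx)
            hi_i = int((x + 6.0 * sigma - grid_lo) / grid_dx) + 1
            if lo_i < 0:
                lo_i = 0
            if hi_i > ngrid - 1:
                hi_i = ngrid - 1
            for i in range(lo_i, hi_i + 1):
                xg = grid_lo + i * grid_dx
                e = h * np.exp(-0.5 * (xg - x) * (xg - x) * inv_sig2)
                vgrid[i] += e
                fgrid[i] += e * (xg - x) * inv_sig2

    return (0, -1, n_saved, n_hills, released, first_cross, alpha_cross,
            sum_expv, steps_done, x, v)


@njit(cache=True)
def _first_passage_od(x0, n_max, dt, mass, gamma, kbt_val, seed,
                      amps, cens, wids, wall_lo, k_lo, wall_hi, k_hi,
                      absorbing):
    """Overdamped Euler–Maruyama first-passage time to `absorbing`, ps.

    Returns -1.0 if not absorbed within n_max steps.
    """
    np.random.seed(seed)
    c = KCAL_PER_AMU_A2_PS2
    diff = kbt_val / (mass * c * gamma)
    sig = np.sqrt(2.0 * diff * dt)
    x = x0
    up = absorbing >= x0
    for step in range(n_max):
        f = _force_1d(x, amps, cens, wids, wall_lo, k_lo, wall_hi, k_hi,
                      0.0, -1.0)
        x = x + f / (mass * c * gamma) * dt + sig * np.random.normal()
        if (up and x >= absorbing) or ((not up) and x <= absorbing):
            return (step + 1) * dt
    return -1.0


def simulate_langevin(landscape, params: LangevinParams, n_steps: int,
                      bias=None, restraints=None, x0: float | None = None,
                      v0: float = 0.0, save_stride: int = 50,
                      integrator: str = "baoab") -> Trajectory:
    """Integrate Langevin dynamics on a 1D landscape.

    Parameters
    ----------
    bias : BiasState, optional
        A frozen external bias: all its hills act for the whole run.
    restraints : list, optional
        Restraint objects with ``.at`` and ``.k`` attributes (upper walls).
    integrator : {"baoab", "euler"}
        BAOAB underdamped splitting (default) or overdamped Euler–Maruyama.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if landscape.dims != 1:
        raise ValueError("the fast integrator is 1D; use simulate_generic for 2D")
    amps, cens, wids = landscape.gaussian_arrays()
    if x0 is None:
        x0 = landscape.default_start
    rest_at, rest_k = 1e30, -1.0
    if restraints:
        if len(restraints) != 1:
            raise ValueError("at most one upper-wall restraint in the fast path")
        rest_at, rest_k = float(restraints[0].at), float(restraints[0].k)
    if bias is not None and len(bias) > 0:
        st_c = np.array([g.center[0] for g in bias.gaussians])
        st_w = np.array([g.width[0] for g in bias.gaussians])
        st_a = np.array([g.height for g in bias.gaussians])
    else:
        st_a = st_c = st_w = _EMPTY
    n_frames = n_steps // save_stride
    out_x = np.empty(max(n_frames, 1))
    out_vb = np.empty_like(out_x)
    res = _run_1d(float(x0), float(v0), int(n_steps), params.timestep,
                  params.mass, params.friction, max(params.kbt, 1e-12),
                  int(params.seed) & 0x7FFFFFFF,
                  amps, cens, wids,
                  landscape.wall_lo, landscape.k_wall,
                  landscape.wall_hi, landscape.k_wall,
                  rest_at, rest_k,
                  st_a, st_c, st_w,
                  int(save_stride),
                  0, 0.0, 1.0, 10.0, 1 << 30,
                  0.0, 1.0, _EMPTY, _EMPTY,
                  _EMPTY, _EMPTY, _EMPTY,
                  0, 0.0, 0.0, 0,
                  1 if integrator == "euler" else 0,
                  out_x, out_vb)
    status, err_step, n_saved = res[0], res[1], res[2]
    if status != 0:
        raise IntegrationError(err_step)
    times = params.timestep * save_stride * np.arange(1, n_saved + 1)
    return Trajectory(times=times, coords=out_x[:n_saved].copy(),
                      cv_labels=("d1",), seed=params.seed)


def simulate_generic(force_fn, x0: np.ndarray, params: LangevinParams,
                     n_steps: int, save_stride: int = 10) -> Trajectory:
    """Overdamped Euler–Maruyama in arbitrary dimension.

    ``force_fn(x) -> force vector`` in kcal/mol/Å.  Slow (Python loop);
    intended for small 2D demonstrations with funnel restraints.
    """
    rng = np.random.default_rng(params.seed)
    x = np.array(x0, dtype=float)
    dims = x.size
    dt = params.timestep
    mob = 1.0 / (params.mass * KCAL_PER_AMU_A2_PS2 * params.friction)
    sig = np.sqrt(2.0 * params.kbt * mob * dt)
    n_frames = n_steps // save_stride
    out = np.empty((n_frames, dims))
    k = 0
    for step in range(n_steps):
        f = np.asarray(force_fn(x), dtype=float)
        if not np.all(np.isfinite(f)):
            raise IntegrationError(step)
        x = x + f * mob * dt + sig * rng.standard_normal(dims)
        if (step + 1) % save_stride == 0 and k < n_frames:
            out[k] = x
            k += 1
    times = dt * save_stride * np.arange(1, k + 1)
    return Trajectory(times=times, coords=out[:k],
                      cv_labels=tuple(f"cv{i+1}" for i in range(dims)),
                      seed=params.seed)
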