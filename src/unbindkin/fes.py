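"""Free-energy surfaces from biased trajectories by histogram reweighting.

Frames from a well-tempered metadynamics run are assigned statistical weights
w ∝ exp((V(s_t, t) - c(t))/kBT), with the time-dependent offset c(t)
computed from the evolving bias as the log-ratio of partition sums

    c(t) = kBT ln [ ∫ e^{γ V(s,t) / ((γ-1) kBT)} ds
                    / ∫ e^{V(s,t) / ((γ-1) kBT)} ds ].

The weighted histogram over any collective variable gives
F = -kBT ln p, min-shifted to zero; stationary points and barriers are
located on the gridded surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .dynamics import Trajectory
from .metad import BiasState


@dataclass
class WeightedSamples:
    """Per-frame CV values with reweighting weights (normalized to mean 1)."""

    values: np.ndarray
    weights: np.ndarray
    kbt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape[0] != self.weights.shape[0]:
            raise ValueError("values and weights must align")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite and non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("need at least one positive weight")


@dataclass
class FreeEnergySurface:
    centers: np.ndarray  # bin centres, Å
    F: np.ndarray  # kcal/mol; +inf on unvisited bins
    bin_width: float
    kbt: float
    min_shifted: bool = True


@dataclass
class FesStates:
    """Labelled stationary points of a 1D FES."""

    minima: list  # (label, position, F)
    maxima: list  # (label, position, F)
    barriers: list  # (from_min_pos, ts_pos, to_min_pos, height)


def _bias_grid(bias: BiasState, grid: np.ndarray, upto_time: float | None = None):
    """Total bias on a grid from hills with time <= upto_time."""
    v = np.zeros_like(grid)
    for g in bias.gaussians:
        if upto_time is not None and g.time > upto_time:
            break
        c, w, h = g.center[0], g.width[0], g.height
        v += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return v


def reweight(trajectory: Trajectory, bias: BiasState, restraints=None,
             kbt: float = 0.5962, restraint_mode: str = "divide",
             grid_dx: float = 0.05) -> WeightedSamples:
    """Tiwary–Parrinello reweighting of a biased trajectory.

    ``restraint_mode='divide'`` removes the restraint Boltzmann factor from
    the sampled ensemble (frames far beyond a wall acquire large weights and
    should be excluded from reported regions); ``'ignore'`` reweights by the
    metadynamics bias only.
    """
    if restraint_mode not in ("divide", "ignore"):
        raise ValueError("restraint_mode must be 'divide' or 'ignore'")
    x = np.asarray(trajectory.coords, dtype=float).ravel()
    t = np.asarray(trajectory.times, dtype=float)
    hills = bias.gaussians
    if hills and hills[-1].time < t[-1] - 1e-9:
        pass  # bias simply stopped early (e.g. release); still valid
    gamma = bias.params.bias_factor
    lo = min(x.min(), min((g.center[0] for g in hills), default=x.min())) - 1.0
    hi = max(x.max(), max((g.center[0] for g in hills), default=x.max())) + 1.0
    grid = np.arange(lo, hi + grid_dx, grid_dx)

    logw = np.empty_like(x)
    vgrid = np.zeros_like(grid)
    # walk frames and hills together in time order
    hi_idx = 0
    n_h = len(hills)
    c_t = 0.0
    for i in range(x.size):
        while hi_idx < n_h and hills[hi_idx].time <= t[i]:
            g = hills[hi_idx]
            vgrid += g.height * np.exp(
                -0.5 * ((grid - g.center[0]) / g.width[0]) ** 2)
            hi_idx += 1
            a = vgrid / kbt / (gamma - 1.0)
            c_t = kbt * (logsumexp(gamma * a) - logsumexp(a))
        v_here = np.interp(x[i], grid, vgrid)
        logw[i] = (v_here - c_t) / kbt
    if restraints and restraint_mode == "divide":
        for r in restraints:
            logw += np.array([r.energy(xi) for xi in x]) / kbt
    logw -= logsumexp(logw) - np.log(x.size)  # normalize to mean 1
    return WeightedSamples(values=x, weights=np.exp(logw), kbt=kbt,
                           meta={"gamma": gamma, "n_hills": n_h,
                                 "restraint_mode": restraint_mode})


def project_fes(samples: WeightedSamples, cv_series=None,
                bins=None, bin_width: float = 0.1,
                range_=None) -> FreeEnergySurface:
    """F = -kBT ln(weighted histogram), min-shifted to zero.

    Empty bins get +inf and are excluded from minimum/barrier searches.
    """
    vals = (np.asarray(cv_series, dtype=float) if cv_series is not None
            else samples.values)
    if vals.shape[0] != samples.weights.shape[0]:
        raise ValueError("cv series length must match the samples")
    if bins is None:
        lo, hi = (range_ if range_ is not None
                  else (vals.min() - 1e-9, vals.max() + 1e-9))
        bins = np.arange(lo, hi + bin_width, bin_width)
    hist, edges = np.histogram(vals, bins=bins, weights=samples.weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        F = -samples.kbt * np.log(hist)
    visited = np.isfinite(F)
    if not visited.any():
        raise ValueError("no visited bins")
    F = F - F[visited].min()
    F[~visited] = np.inf
    return FreeEnergySurface(centers=centers, F=F,
                             bin_width=float(edges[1] - edges[0]),
                             kbt=samples.kbt)


def find_states_and_barriers(fes: FreeEnergySurface, smooth_bins: int = 0,
                             min_prominence: float = 1e-4) -> FesStates:
    """Locate minima/maxima of a gridded FES.

    Optional moving-average smoothing over `smooth_bins` bins (0 = none);
    extrema whose prominence falls below `min_prominence` (kcal/mol) are
    suppressed — raise it toward ~kBT/2 for statistically noisy surfaces.
    The lowest minimum is labelled ``global_min``; maxima between adjacent
    minima are ``TS1``, ``TS2``, ... in order of position, and barrier
    heights are measured from the preceding minimum.
    """
    from .landscapes import alternating_extrema

    F = fes.F.copy()
    x = fes.centers
    finite = np.isfinite(F)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite bins")
    if smooth_bins and smooth_bins > 1:
        k = np.ones(smooth_bins) / smooth_bins
        Fs = F.copy()
        Fs[finite] = np.convolve(F[finite], k, mode="same")
        F = Fs
    xs, fs_ = x[finite], F[finite]
    ext = alternating_extrema(fs_, tol=min_prominence)
    minima = [(xs[i], fs_[i]) for kind, i in ext if kind == "min"]
    maxima = [(xs[i], fs_[i]) for kind, i in ext if kind == "max"]
    if not minima:
        # monotone surface: the lowest bin is the only basin, no TS
        minima = [(xs[int(np.argmin(fs_))], float(np.min(fs_)))]
    gmin_pos = min(minima, key=lambda p: p[1])[0]
    lab_minima = []
    k_extra = 2
    for pos, f in minima:
        if pos == gmin_pos:
            lab_minima.append(("global_min", pos, f))
        else:
            lab_minima.append((f"min{k_extra}", pos, f))
            k_extra += 1
    barriers = []
    lab_maxima = []
    mins_sorted = sorted(minima)
    ts_i = 1
    for (x0, f0), (x1, f1) in zip(mins_sorted[:-1], mins_sorted[1:]):
        between = [(p, f) for p, f in maxima if x0 < p < x1]
        if not between:
            continue
        ts_pos, ts_f = max(between, key=lambda p: p[1])
        lab_maxima.append((f"TS{ts_i}", ts_pos, ts_f))
        barriers.append((x0, ts_pos, x1, ts_f - f0))
        ts_i += 1
    return FesStates(minima=lab_minima, maxima=lab_maxima, barriers=barriers)


def convergence_curves(trajectory: Trajectory, bias: BiasState,
                       basin_a: tuple, basin_b: tuple, checkpoints,
                       kbt: float = 0.5962, restraints=None,
                       bin_width: float = 0.1) -> dict:
    """Free-energy difference and barrier between two basins vs time.

    For each checkpoint time (ps) the FES is recomputed from frames up to
    that time;  dG(A,B) = -kBT ln(sum_A e^{-F/kBT} / sum_B e^{-F/kBT}); the
    barrier is the highest surface point between the basins minus the basin-A
    floor.  A basin not yet visited yields NaN for that checkpoint.
    """
    a_lo, a_hi = basin_a
    b_lo, b_hi = basin_b
    if not (a_hi <= b_lo or b_hi <= a_lo):
        raise ValueError("basin windows must be disjoint")
    t = np.asarray(trajectory.times)
    checkpoints = np.atleast_1d(np.asarray(checkpoints, dtype=float))
    dgs, barriers = [], []
    for tc in checkpoints:
        m = t <= tc
        if m.sum() < 2:
            dgs.append(np.nan)
            barriers.append(np.nan)
            continue
        sub = Trajectory(times=t[m], coords=trajectory.coords[m],
                         cv_labels=trajectory.cv_labels, seed=trajectory.seed)
        samples = reweight(sub, _bias_upto(bias, tc), restraints=restraints,
                           kbt=kbt)
        fes = project_fes(samples, bin_width=bin_width)
        xa = (fes.centers >= a_lo) & (fes.centers <= a_hi) & np.isfinite(fes.F)
        xb = (fes.centers >= b_lo) & (fes.centers <= b_hi) & np.isfinite(fes.F)
        if not xa.any() or not xb.any():
            dgs.append(np.nan)
            barriers.append(np.nan)
            continue
        za = logsumexp(-fes.F[xa] / kbt)
        zb = logsumexp(-fes.F[xb] / kbt)
        dgs.append(float(-kbt * (za - zb)))
        lo = min(a_hi, b_hi)
        hi = max(a_lo, b_lo)
        mid = (fes.centers > lo) & (fes.centers < hi) & np.isfinite(fes.F)
        if mid.any():
            barriers.append(float(fes.F[mid].max() - fes.F[xa].min()))
        else:
            barriers.append(np.nan)
    return {"checkpoints": checkpoints, "dG": np.array(dgs),
            "barrier": np.array(barriers)}


def _bias_upto(bias: BiasState, tc: float) -> BiasState:
    sub = BiasState(params=bias.params)
    sub.gaussians = [g for g in bias.gaussians if g.time <= tc]
    return sub


def extract_state_frames(trajectory: Trajectory, center: float,
                         tolerance: float = 0.01,
                         cv_series=None) -> np.ndarray:
    """Frame indices with |cv - center| <= tolerance.

    The narrow 0.01 Å default suits densely saved trajectories; widen it for
    coarse ones.  Returns an empty array (with a warning) if nothing matches.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cv = (np.asarray(cv_series, dtype=float) if cv_series is not None
          else np.asarray(trajectory.coords, dtype=float).ravel())
    idx = np.where(np.abs(cv - center) <= tolerance)[0]
    if idx.size == 0:
        warnings.warn(f"no frames within {tolerance} Å of {center} Å",
                      RuntimeWarning)
    return idx


def write_fes(path, fes: FreeEnergySurface, comment: str = "") -> None:
    """Two-column text (CV Å, F kcal/mol) with header metadata."""
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS cv free_energy\n# bin_width {fes.bin_width:.6g}"
                 f" kbt {fes.kbt:.6g} min_shifted {fes.min_shifted}\n")
        if comment:
            fh.write(f"# {comment}\n")
        for c, f in zip(fes.centers, fes.F):
            fh.write(f"{c:.17g} {f:.17g}\n")
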