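"""Markov state models on 1D distance trajectories.

Swarms of short unbiased trajectories of the ligand–active-site distance are
clustered into microstates (mini-batch k-means), a lag-time transition matrix
is estimated with sliding-window counts, microstates are grouped into three
macrostates (bound / tunnel / unbound) by distance thresholds, and kinetics
follow from mean first-passage times and stationary probabilities.

Note on affinities: the association rate in molar units requires an effective
ligand concentration C (one molecule per simulation volume); it is a required
input, never a hidden constant.  Two affinity measures are reported, as they
differ in general: the kinetic ratio k_off/k_on and the equilibrium
K_d = C * pi_unbound / pi_bound from stationary probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import MiniBatchKMeans

from .units import KB_KCAL, NS_PER_S


class MsmError(RuntimeError):
    pass


@dataclass
class FeaturizedEnsemble:
    """Equal-stride 1D distance time series (Å).

    Series shorter than `min_length_ns` are excluded at construction
    (mirrors discarding unsuccessful short simulations).
    """

    series: list
    frame_interval: float  # ns between saved frames
    min_length_ns: float = 20.0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        kept = []
        self.n_excluded = 0
        for s in self.series:
            s = np.asarray(s, dtype=float).ravel()
            if s.size * self.frame_interval < self.min_length_ns:
                self.n_excluded += 1
            else:
                kept.append(s)
        self.series = kept

    def __len__(self):
        return len(self.series)

    @property
    def n_frames(self):
        return sum(s.size for s in self.series)


@dataclass
class ClusterModel:
    n_clusters: int
    centers: np.ndarray  # sorted ascending, Å
    assignments: list  # per trajectory, int arrays

    def assign(self, series) -> np.ndarray:
        """Nearest-centre assignment; ties break toward the lower index."""
        x = np.asarray(series, dtype=float).ravel()
        d = np.abs(x[:, None] - self.centers[None, :])
        return np.argmin(d, axis=1)


def cluster(ensemble: FeaturizedEnsemble, n_clusters: int = 200,
            seed: int = 0) -> ClusterModel:
    """Mini-batch k-means microstate clustering of the 1D feature."""
    data = np.concatenate([s for s in ensemble.series])
    if data.size < n_clusters:
        raise MsmError("fewer frames than requested clusters")
    n_unique = np.unique(data).size
    k = n_clusters
    if n_unique < n_clusters:
        warnings.warn(f"only {n_unique} unique values; reducing k", RuntimeWarning)
        k = n_unique
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=5,
                         batch_size=4096, max_no_improvement=50)
    km.fit(data.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    model = ClusterModel(n_clusters=k, centers=centers, assignments=[])
    model.assignments = [model.assign(s) for s in ensemble.series]
    return model


@dataclass
class MarkovModel:
    lag_ns: float
    frame_interval: float  # ns
    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    stationary: np.ndarray
    centers: np.ndarray  # active microstate centres, Å
    active: np.ndarray  # indices into the original cluster set
    dtrajs: list  # remapped discrete trajectories (active-state indices)
    macrostates: np.ndarray | None = None  # per active microstate: 0/1/2
    boundaries: tuple | None = None
    mode: str = "symmetrized"
    temperature: float = 300.0

    @property
    def lag_frames(self) -> int:
        return int(round(self.lag_ns / self.frame_interval))


MACROSTATE_NAMES = ("bound", "tunnel", "unbound")


def _count_matrix(dtrajs, n_states, lag_frames):
    c = np.zeros((n_states, n_states))
    for d in dtrajs:
        if d.size > lag_frames:
            np.add.at(c, (d[:-lag_frames], d[lag_frames:]), 1.0)
    return c


def _stationary(T):
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_transition_matrix(ensemble: FeaturizedEnsemble,
                               clusters: ClusterModel, lag: float = 15.0,
                               mode: str = "symmetrized",
                               temperature: float = 300.0) -> MarkovModel:
    """Sliding-window transition counts at the given lag (ns), row-normalized.

    ``symmetrized`` enforces detailed balance via (C + C^T)/2 before
    normalization; ``mle`` row-normalizes the raw counts.  Unvisited states
    and states with empty rows are dropped with a warning and indices
    remapped.
    """
    if mode not in ("mle", "symmetrized"):
        raise ValueError("mode must be 'mle' or 'symmetrized'")
    ratio = lag / ensemble.frame_interval
    lag_frames = int(round(ratio))
    if abs(ratio - lag_frames) > 1e-6 or lag_frames < 1:
        raise ValueError("lag must be a positive multiple of the frame interval")
    if not any(d.size > lag_frames for d in clusters.assignments):
        raise MsmError("every trajectory is shorter than the lag")
    n = clusters.centers.size
    c = _count_matrix(clusters.assignments, n, lag_frames)
    csym = 0.5 * (c + c.T) if mode == "symmetrized" else c
    rows = csym.sum(axis=1)
    active = np.where(rows > 0)[0]
    if active.size < n:
        warnings.warn(f"dropping {n - active.size} unvisited/empty states",
                      RuntimeWarning)
    csym = csym[np.ix_(active, active)]
    rows = csym.sum(axis=1)
    if np.any(rows == 0):
        raise MsmError("empty row after state removal")
    T = csym / rows[:, None]
    if mode == "symmetrized":
        pi = rows / rows.sum()
    else:
        pi = _stationary(T)
    remap = -np.ones(n, dtype=int)
    remap[active] = np.arange(active.size)
    dtrajs = [remap[d] for d in clusters.assignments]
    return MarkovModel(lag_ns=lag, frame_interval=ensemble.frame_interval,
                       count_matrix=c[np.ix_(active, active)],
                       transition_matrix=T, stationary=pi,
                       centers=clusters.centers[active], active=active,
                       dtrajs=dtrajs, mode=mode, temperature=temperature)


def define_macrostates(model: MarkovModel,
                       boundaries: tuple = (5.0, 15.0)) -> MarkovModel:
    """Group microstates into bound / tunnel / unbound by distance.

    Centres <= bound_max are bound (0), >= unbound_min are unbound (2),
    the rest is the tunnel intermediate (1).
    """
    bound_max, unbound_min = boundaries
    if bound_max >= unbound_min:
        raise ValueError("bound_max must be below unbound_min")
    macro = np.where(model.centers <= bound_max, 0,
                     np.where(model.centers >= unbound_min, 2, 1))
    for m, name in enumerate(MACROSTATE_NAMES):
        if not np.any(macro == m):
            raise MsmError(f"macrostate '{name}' is empty for boundaries "
                           f"{boundaries}")
    model.macrostates = macro
    model.boundaries = tuple(boundaries)
    return model


def mfpt(model: MarkovModel, from_macro: int, to_macro: int) -> float:
    """Mean first-passage time (ns) between macrostates.

    Solves the microstate linear system (I - T_QQ) m = lag * 1 over states
    outside the target and averages over the source macrostate weighted by
    the stationary distribution restricted to it.
    """
    if model.macrostates is None:
        raise MsmError("macrostates not defined")
    macro = model.macrostates
    target = np.where(macro == to_macro)[0]
    source = np.where(macro == from_macro)[0]
    if target.size == 0 or source.size == 0:
        raise MsmError("empty macrostate")
    q = np.where(macro != to_macro)[0]
    T = model.transition_matrix
    A = np.eye(q.size) - T[np.ix_(q, q)]
    try:
        m_q = np.linalg.solve(A, model.lag_ns * np.ones(q.size))
    except np.linalg.LinAlgError as exc:
        raise MsmError("target unreachable (singular system)") from exc
    if np.any(m_q < -1e-9) or not np.all(np.isfinite(m_q)):
        raise MsmError("invalid first-passage solution; chain may be reducible")
    m_full = np.zeros(macro.size)
    m_full[q] = m_q
    w = model.stationary[source]
    return float(np.dot(w / w.sum(), m_full[source]))


@dataclass
class KineticEstimates:
    tau_off: float  # ns
    k_off: float  # s^-1
    tau_on: float  # ns
    k_on: float  # M^-1 s^-1
    koff_over_kon: float  # M; = k_off/k_on identically
    Kd: float  # M; C * pi_unbound / pi_bound
    dG: float  # kcal/mol
    concentration: float  # M
    sds: dict = field(default_factory=dict)


def kinetics(model: MarkovModel, concentration: float,
             standard_state: bool = False) -> KineticEstimates:
    """Derive rates and affinities from the macrostate-coarse model.

    tau_off/tau_on are bound->unbound / unbound->bound MFPTs; k_on is
    normalized by the effective ligand concentration C (M, required);
    dG = -kBT ln(pi_bound/pi_unbound), with an optional kBT ln(C/1M)
    standard-state term.
    """
    if model.macrostates is None:
        raise MsmError("macrostates not defined")
    if concentration <= 0:
        raise ValueError("effective concentration must be positive (M)")
    pi_b = float(model.stationary[model.macrostates == 0].sum())
    pi_u = float(model.stationary[model.macrostates == 2].sum())
    if pi_b <= 0 or pi_u <= 0:
        raise MsmError("zero stationary mass in bound or unbound macrostate")
    tau_off = mfpt(model, 0, 2)
    tau_on = mfpt(model, 2, 0)
    k_off = NS_PER_S / tau_off
    k_on = NS_PER_S / (tau_on * concentration)
    kbt = KB_KCAL * model.temperature
    dG = -kbt * np.log(pi_b / pi_u)
    if standard_state:
        dG += kbt * np.log(concentration)
    return KineticEstimates(tau_off=tau_off, k_off=k_off, tau_on=tau_on,
                            k_on=k_on, koff_over_kon=k_off / k_on,
                            Kd=concentration * pi_u / pi_b, dG=float(dG),
                            concentration=concentration)


def chapman_kolmogorov(model: MarkovModel, k_steps=(1, 2, 3, 4, 5)) -> dict:
    """Chapman–Kolmogorov test on macrostate self-transition probabilities.

    Compares T(lag)^k with a re-estimated T(k*lag) for each k; returns per
    macrostate the predicted/re-estimated curves and absolute deviations.
    Ks whose lag exceeds the data are dropped with a warning.
    """
    if model.macrostates is None:
        raise MsmError("macrostates not defined")
    max_len = max(d.size for d in model.dtrajs)
    usable = [k for k in k_steps if k * model.lag_frames < max_len]
    if len(usable) < len(k_steps):
        warnings.warn("truncating k list: insufficient trajectory length",
                      RuntimeWarning)
    n = model.centers.size
    macro = model.macrostates
    pi = model.stationary
    out = {name: {"k": [], "predicted": [], "estimated": [], "deviation": []}
           for name in MACROSTATE_NAMES}
    Tk = np.eye(n)
    for k in range(1, max(usable) + 1):
        Tk = Tk @ model.transition_matrix
        if k not in usable:
            continue
        c = _count_matrix(model.dtrajs, n, k * model.lag_frames)
        if model.mode == "symmetrized":
            c = 0.5 * (c + c.T)
        rows = c.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Test = np.where(rows[:, None] > 0, c / rows[:, None], 0.0)
        for m, name in enumerate(MACROSTATE_NAMES):
            idx = np.where(macro == m)[0]
            w = pi[idx] / pi[idx].sum()
            p_pred = float(w @ Tk[np.ix_(idx, idx)].sum(axis=1))
            p_est = float(w @ Test[np.ix_(idx, idx)].sum(axis=1))
            out[name]["k"].append(k)
            out[name]["predicted"].append(p_pred)
            out[name]["estimated"].append(p_est)
            out[name]["deviation"].append(abs(p_pred - p_est))
    return out


def bootstrap_msm(ensemble: FeaturizedEnsemble, clusters: ClusterModel,
                  concentration: float, lag: float = 15.0,
                  boundaries: tuple = (5.0, 15.0), fraction: float = 0.8,
                  n_boot: int = 500, seed: int = 0,
                  mode: str = "symmetrized",
                  temperature: float = 300.0) -> dict:
    """Bootstrap SDs for all kinetic estimates.

    Each replicate draws `fraction` of the trajectory list without
    replacement, re-estimates the transition matrix on the fixed microstate
    definition, and recomputes the kinetics; replicates with an empty
    macrostate are skipped and counted.
    """
    n_traj = len(ensemble.series)
    if n_traj < 5:
        raise MsmError("need at least 5 trajectories to bootstrap")
    rng = np.random.default_rng(seed)
    n_pick = max(int(round(fraction * n_traj)), 2)
    samples = {k: [] for k in ("tau_off", "k_off", "tau_on", "k_on",
                               "koff_over_kon", "Kd", "dG")}
    skipped = 0
    for _ in range(n_boot):
        idx = rng.choice(n_traj, size=n_pick, replace=False)
        sub_ens = FeaturizedEnsemble([ensemble.series[i] for i in idx],
                                     ensemble.frame_interval,
                                     min_length_ns=0.0)
        sub_cl = ClusterModel(clusters.n_clusters, clusters.centers,
                              [clusters.assignments[i] for i in idx])
        try:
            m = estimate_transition_matrix(sub_ens, sub_cl, lag=lag,
                                           mode=mode, temperature=temperature)
            m = define_macrostates(m, boundaries)
            est = kinetics(m, concentration)
        except (MsmError, np.linalg.LinAlgError):
            skipped += 1
            continue
        for k in samples:
            samples[k].append(getattr(est, k))
    sds = {k: (float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
           for k, v in samples.items()}
    sds["n_replicates"] = len(samples["k_off"])
    sds["n_skipped"] = skipped
    return sds
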