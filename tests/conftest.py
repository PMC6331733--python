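"""Shared fixtures: model landscapes and the expensive simulation products
(release ensembles, unbiased swarms, well-tempered FES runs) reused across
test modules."""

import warnings

import numpy as np
import pytest

import unbindkin as uk
from unbindkin import fes, msm
from unbindkin.cvs import UpperWall

KBT300 = 0.59616


@pytest.fixture(scope="session")
def doublewell():
    """Symmetric double well with a 5 kBT barrier (oracle test system)."""
    return uk.build_doublewell(5 * KBT300)


@pytest.fixture(scope="session")
def presets():
    return {name: uk.build_preset_landscape(name)
            for name in ("dhaa31like", "dhaawtlike", "doublewell", "flat")}


@pytest.fixture(scope="session")
def dw_release_ensemble(doublewell):
    """25 infrequent-MTD release runs on the double well (threshold 20 Å)."""
    p = uk.LangevinParams(seed=9)
    wt = uk.WellTemperedParams()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return uk.ensemble_release(doublewell, p, wt, n_runs=25,
                                   threshold=20.0, max_time=1e6)


@pytest.fixture(scope="session")
def dw_swarm(doublewell):
    """Swarm of 60 × 10 ns unbiased trajectories on the double well,
    0.01 ns frame interval, starts spread over the domain."""
    rng = np.random.default_rng(7)
    starts = [8.0] * 30 + [16.0] * 20 + [21.0] * 10
    series = []
    for s in starts:
        p = uk.LangevinParams(seed=int(rng.integers(2**31)))
        tr = uk.simulate_langevin(doublewell, p, 500_000, x0=s,
                                  save_stride=500)
        series.append(tr.coords)
    return msm.FeaturizedEnsemble(series, frame_interval=0.01,
                                  min_length_ns=5.0)


@pytest.fixture(scope="session")
def dw_msm(dw_swarm):
    cl = msm.cluster(dw_swarm, n_clusters=200, seed=1)
    m = msm.estimate_transition_matrix(dw_swarm, cl, lag=0.02)
    return msm.define_macrostates(m, (10.0, 19.5))


def run_wt_fes(landscape, seed, total_time=8.0e4):
    """Well-tempered wall-restrained run + reweighted FES on d1."""
    p = uk.LangevinParams(seed=seed)
    wt = uk.WellTemperedParams(stride=2.0)
    wall = UpperWall(at=23.0, k=12.0)
    traj, bias = uk.metad.run_metadynamics(landscape, p, wt,
                                           total_time=total_time,
                                           restraints=[wall], save_stride=25)
    samples = fes.reweight(traj, bias, restraints=[wall], kbt=landscape.kbt)
    surface = fes.project_fes(samples, bin_width=0.1,
                              range_=(landscape.wall_lo, 23.0))
    return traj, bias, samples, surface


@pytest.fixture(scope="session")
def dw_wt_fes(doublewell):
    return run_wt_fes(doublewell, seed=3)
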