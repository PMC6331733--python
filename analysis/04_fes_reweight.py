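#!/usr/bin/env python
"""Stage 4 — free-energy surfaces from well-tempered runs.

Runs wall-restrained well-tempered metadynamics on each release preset with
many unbind/rebind recrossings, reweights the trajectory to the unbiased
ensemble, projects the FES on the distance coordinate, locates states and
barriers, tracks basin-difference and barrier convergence with simulation
time, and extracts the frame ensembles of the global minimum and TS1.

Writes fes_<system>.dat, fes_states.json, convergence curves and a figure.
"""

import argparse
import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import unbindkin as uk
from unbindkin import fes
from unbindkin.cvs import UpperWall

OUT = Path(__file__).resolve().parents[1] / "results"
KBT = uk.units.kbt(300.0)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--time-ps", type=float, default=8e4)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(args.seed)
    wall = UpperWall(at=23.0, k=12.0)
    wt = uk.WellTemperedParams(stride=2.0)
    states_out = {}
    surfaces = {}
    for name in ("dhaa31like", "dhaawtlike", "doublewell"):
        L = uk.build_preset_landscape(name)
        p = uk.LangevinParams(seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj, bias = uk.metad.run_metadynamics(
                L, p, wt, total_time=args.time_ps, restraints=[wall],
                save_stride=25)
            samples = fes.reweight(traj, bias, restraints=[wall], kbt=KBT)
            surface = fes.project_fes(samples, bin_width=0.1,
                                      range_=(L.wall_lo, 20.0))
            st = fes.find_states_and_barriers(surface, min_prominence=0.3)
            basins = ((st.minima[0][1] - 1.0, st.minima[0][1] + 1.0),
                      (st.minima[-1][1] - 1.0, st.minima[-1][1] + 1.0))
            conv = fes.convergence_curves(
                traj, bias, basins[0], basins[1],
                checkpoints=np.linspace(args.time_ps / 8, args.time_ps, 8),
                kbt=KBT, restraints=[wall])
        fes.write_fes(OUT / f"fes_{name}.dat", surface,
                      comment=f"reweighted FES, {args.time_ps/1000:.0f} ns")
        gmin = next(m for m in st.minima if m[0] == "global_min")
        ts1 = st.maxima[0] if st.maxima else None
        frames = {
            "global_min": fes.extract_state_frames(
                traj, center=gmin[1], tolerance=0.05).tolist()[:50],
        }
        if ts1:
            frames["TS1"] = fes.extract_state_frames(
                traj, center=ts1[1], tolerance=0.05).tolist()[:50]
        states_out[name] = {
            "minima": [(lab, round(float(x), 2), round(float(f), 3))
                       for lab, x, f in st.minima],
            "maxima": [(lab, round(float(x), 2), round(float(f), 3))
                       for lab, x, f in st.maxima],
            "barriers_kcal": [round(float(b[3]), 3) for b in st.barriers],
            "n_state_frames": {k: len(v) for k, v in frames.items()},
            "dG_convergence": [None if np.isnan(v) else round(float(v), 3)
                               for v in conv["dG"]],
            "barrier_convergence": [None if np.isnan(v)
                                    else round(float(v), 3)
                                    for v in conv["barrier"]],
        }
        surfaces[name] = surface
        print(f"{name}: minima at "
              f"{[round(float(x), 2) for _, x, _ in st.minima]} Å, "
              f"barriers {states_out[name]['barriers_kcal']} kcal/mol, "
              f"final dG(A,B) {states_out[name]['dG_convergence'][-1]}")
    with open(OUT / "fes_states.json", "w") as fh:
        json.dump(states_out, fh, indent=2)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, surface in surfaces.items():
            m = np.isfinite(surface.F)
            ax.plot(surface.centers[m], surface.F[m], label=name)
        ax.set_xlabel("d1 [Å]")
        ax.set_ylabel("free energy [kcal/mol]")
        ax.legend()
        fig.tight_layout()
        fig.savefig(OUT / "fes_projected_d1.png", dpi=120)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
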