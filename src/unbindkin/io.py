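"""Columnar text I/O (COLVAR/HILLS dialects) and run configuration.

The dialects follow the PLUMED convention: a ``#! FIELDS <names...>`` header
line followed by whitespace-separated float rows.  Floats are rendered with
17 significant digits so read(write(x)) round-trips bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .metad import BiasState, Hill, WellTemperedParams


class ParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _read_columnar(path):
    fields = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#!"):
                parts = s.split()
                if len(parts) < 3 or parts[1] != "FIELDS":
                    raise ParseError(path, lineno, "malformed FIELDS header")
                fields = parts[2:]
                continue
            if s.startswith("#"):
                continue
            if fields is None:
                raise ParseError(path, lineno, "data before FIELDS header")
            vals = s.split()
            if len(vals) != len(fields):
                raise ParseError(path, lineno,
                                 f"expected {len(fields)} columns, got {len(vals)}")
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric value") from None
    if fields is None:
        raise ParseError(path, 0, "missing FIELDS header")
    return pd.DataFrame(np.array(rows).reshape(-1, len(fields)), columns=fields)


def _write_columnar(path, df: pd.DataFrame):
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_colvar(path) -> pd.DataFrame:
    """Read a COLVAR-dialect file; first column must be strictly increasing
    time."""
    df = _read_columnar(path)
    if df.columns[0] != "time":
        raise ParseError(path, 1, "first field must be 'time'")
    t = df["time"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ParseError(path, 0, "time must be strictly increasing")
    return df


def write_colvar(path, trajectory: Trajectory) -> None:
    cols = {"time": trajectory.times}
    coords = np.atleast_2d(trajectory.coords.T).T
    if coords.ndim == 1:
        coords = coords[:, None]
    for j, lab in enumerate(trajectory.cv_labels):
        cols[lab] = coords[:, j]
    _write_columnar(path, pd.DataFrame(cols))


def colvar_to_trajectory(df: pd.DataFrame, seed: int = 0) -> Trajectory:
    labels = tuple(c for c in df.columns if c != "time")
    coords = df[list(labels)].to_numpy()
    if coords.shape[1] == 1:
        coords = coords.ravel()
    return Trajectory(times=df["time"].to_numpy(), coords=coords,
                      cv_labels=labels, seed=seed)


def write_hills(path, bias: BiasState) -> None:
    t, c, w, h = bias.arrays()
    cols = {"time": t}
    d = c.shape[1] if len(t) else 1
    for j in range(d):
        cols[f"center_{j+1}"] = c[:, j] if len(t) else np.empty(0)
    for j in range(d):
        cols[f"sigma_{j+1}"] = w[:, j] if len(t) else np.empty(0)
    cols["height"] = h
    cols["biasf"] = np.full_like(h, bias.params.bias_factor)
    _write_columnar(path, pd.DataFrame(cols))


def read_hills(path, params: WellTemperedParams | None = None) -> BiasState:
    df = _read_columnar(path)
    cen_cols = [c for c in df.columns if c.startswith("center_")]
    sig_cols = [c for c in df.columns if c.startswith("sigma_")]
    if not cen_cols or len(cen_cols) != len(sig_cols) or "height" not in df:
        raise ParseError(path, 1, "expected center_*/sigma_*/height fields")
    if params is None:
        biasf = float(df["biasf"].iloc[0]) if "biasf" in df and len(df) else 10.0
        params = WellTemperedParams(bias_factor=biasf)
    bias = BiasState(params=params)
    for row in df.itertuples(index=False):
        rd = row._asdict()
        if rd["height"] <= 0:
            raise ParseError(path, 0, "non-positive hill height")
        bias.append(Hill(time=rd["time"],
                         center=tuple(rd[c] for c in cen_cols),
                         width=tuple(rd[c] for c in sig_cols),
                         height=rd["height"]))
    return bias


# ---------------------------------------------------------------------------
# Run configuration

_CONFIG_SCHEMA = {
    "landscape": {"preset", "temperature", "wall_hi", "wall_lo", "barrier",
                  "asymmetry"},
    "langevin": {"timestep", "friction", "mass", "temperature", "seed"},
    "metadynamics": {"height0", "sigma", "stride", "bias_factor"},
    "release": {"threshold", "rebind_floor", "commit_window", "max_time",
                "n_runs"},
    "msm": {"n_clusters", "lag", "bound_max", "unbound_min", "concentration",
            "frame_interval", "min_length_ns", "n_boot", "fraction"},
    "fes": {"bin_width", "smooth_bins", "restraint_mode"},
    "hotspots": {"threshold"},
    "output": {"directory"},
    "seed": None,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    sections: dict = field(default_factory=dict)
    seed: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        seed = int(raw.pop("seed", 1))
        for sec, keys in raw.items():
            if sec not in _CONFIG_SCHEMA:
                raise ValueError(f"unknown config section {sec!r}")
            allowed = _CONFIG_SCHEMA[sec]
            for k in keys:
                if k not in allowed:
                    raise ValueError(f"unknown key {sec}.{k}")
        return cls(sections=raw, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)

    def dump(self, path) -> None:
        """Archive the resolved configuration next to the run outputs."""
        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed, **self.sections}, fh,
                           sort_keys=True)
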