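"""Per-residue interaction-energy statistics and hot-spot ranking.

Given per-frame, per-residue ligand interaction energies for two state
ensembles of the unbinding free-energy surface — the global minimum and the
first transition state (TS1) — the statistic ΔΔG_bind = ΔG^min − ΔG^TS1
ranks residues by how strongly they retain the ligand in the bound minimum
relative to the transition state.  The most negative values nominate
mutagenesis hot-spots for accelerating release; strong TS1 binders are
candidate targets for lowering the transition-state energy instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class HotspotReport:
    """Per-residue state means/SDs, ΔΔG, and the display flag."""

    table: pd.DataFrame  # index: residue; columns: mean_min, sd_min,
    #                      mean_ts1, sd_ts1, ddg, flagged
    threshold: float = 0.5  # kcal/mol display rule

    @property
    def ranking(self) -> list:
        """Residues ordered by ascending ΔΔG (most negative first)."""
        return list(self.table.sort_values("ddg").index)

    @property
    def flagged(self) -> list:
        return list(self.table.index[self.table["flagged"]])

    def to_text(self) -> str:
        cols = ["mean_min", "sd_min", "mean_ts1", "sd_ts1", "ddg", "flagged"]
        df = self.table.sort_values("ddg")[cols]
        lines = [f"# ddG_bind = dG(min) - dG(TS1); display rule: |ddG| or SD"
                 f" >= {self.threshold} kcal/mol",
                 f"{'residue':<10}" + "".join(f"{c:>10}" for c in cols)]
        for res, row in df.iterrows():
            lines.append(f"{res:<10}" + "".join(
                f"{row[c]:>10.3f}" if c != "flagged" else f"{str(row[c]):>10}"
                for c in cols))
        return "\n".join(lines) + "\n"


def ensemble_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Column (per-residue) means and sample SDs of an energy table."""
    if len(table) < 2:
        raise ValueError("need at least 2 frames")
    return pd.DataFrame({"mean": table.mean(axis=0),
                         "sd": table.std(axis=0, ddof=1)})


def delta_delta_g(min_table: pd.DataFrame, ts1_table: pd.DataFrame,
                  threshold: float = 0.5) -> HotspotReport:
    """ΔΔG = mean(min) − mean(TS1) per residue, ranked ascending.

    A residue is display-flagged when |ΔΔG| >= threshold or when the pooled
    SD (max of the two state SDs) >= threshold.
    """
    a = set(min_table.columns)
    b = set(ts1_table.columns)
    if a != b:
        raise ValueError(f"residue sets differ: only-min={sorted(a - b)}, "
                         f"only-ts1={sorted(b - a)}")
    s_min = ensemble_stats(min_table)
    s_ts1 = ensemble_stats(ts1_table).loc[s_min.index]
    ddg = s_min["mean"] - s_ts1["mean"]
    pooled_sd = np.maximum(s_min["sd"], s_ts1["sd"])
    flagged = (ddg.abs() >= threshold) | (pooled_sd >= threshold)
    tab = pd.DataFrame({"mean_min": s_min["mean"], "sd_min": s_min["sd"],
                        "mean_ts1": s_ts1["mean"], "sd_ts1": s_ts1["sd"],
                        "ddg": ddg, "flagged": flagged})
    return HotspotReport(table=tab.sort_values("ddg"), threshold=threshold)


def transition_state_binders(ts1_table: pd.DataFrame,
                             threshold: float = 0.5) -> list:
    """Residues binding strongly in TS1: mean ΔG <= -threshold, ranked by
    increasing mean (strongest binder first)."""
    stats = ensemble_stats(ts1_table)
    strong = stats[stats["mean"] <= -threshold].sort_values("mean")
    return list(strong.index)


def read_energy_table(path) -> pd.DataFrame:
    """Columnar text: header row of residue labels (first column = frame id),
    then one row of energies per frame."""
    df = pd.read_csv(path, sep=r"\s+", comment=None)
    return df.set_index(df.columns[0]).astype(float)


def write_energy_table(path, table: pd.DataFrame, state: str = "state") -> None:
    out = table.copy()
    out.insert(0, "frame", np.arange(len(out)))
    out.to_csv(path, sep=" ", index=False, float_format="%.8g")
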