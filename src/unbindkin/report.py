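"""Comparative kinetics report.

Collects per-system kinetic quantities (tau_off, k_off, tau_on, k_on,
k_off/k_on, K_d, dG with SDs), derives missing rates from transition times,
and renders a text/JSON comparison including the cross-system relative
k_off — always recomputed from the stored rates, never stored independently.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .kinetics import koff_from_tau

ROWS = [("tau_off_ns", "tau_off [ns]"), ("k_off", "k_off [1/s]"),
        ("tau_on_ns", "tau_on [ns]"), ("k_on", "k_on [1/(M s)]"),
        ("koff_over_kon", "k_off/k_on [M]"), ("Kd", "K_d [M]"),
        ("dG", "dG_eq [kcal/mol]")]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def _fmt(x: float, sig: int = 3) -> str:
    if x is None:
        return ""
    r = round_sig(x, sig)
    if r != 0 and (abs(r) >= 1e4 or abs(r) < 1e-3):
        return f"{r:.{sig - 1}e}"
    return f"{r:.{sig}g}"


@dataclass
class ComparativeReport:
    systems: dict  # name -> {quantity: value, quantity_sd: value}
    order: list = field(default_factory=list)

    @property
    def relative_k_off(self) -> float | None:
        """k_off(second system) / k_off(first system), recomputed."""
        if len(self.order) < 2:
            return None
        k1 = self.systems[self.order[0]].get("k_off")
        k2 = self.systems[self.order[1]].get("k_off")
        if not k1 or not k2:
            return None
        return k2 / k1

    def to_json(self) -> str:
        payload = {name: dict(vals) for name, vals in self.systems.items()}
        rel = self.relative_k_off
        if rel is not None:
            payload["relative_k_off"] = {
                "value": rel, "ratio": f"{self.order[1]}/{self.order[0]}"}
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self, sig: int = 3) -> str:
        width = max(len(n) for n in self.order) + 2
        lines = ["Comparative unbinding kinetics",
                 f"{'parameter':<22}" + "".join(f"{n:>{width + 12}}"
                                                for n in self.order)]
        for key, label in ROWS:
            if not any(key in self.systems[n] for n in self.order):
                continue
            cells = []
            for n in self.order:
                v = self.systems[n].get(key)
                sd = self.systems[n].get(key + "_sd")
                cell = _fmt(v, sig) if v is not None else ""
                if v is not None and sd is not None:
                    cell += f" ± {_fmt(sd, 2)}"
                cells.append(f"{cell:>{width + 12}}")
            lines.append(f"{label:<22}" + "".join(cells))
        rel = self.relative_k_off
        if rel is not None:
            lines.append(f"{'Rel. k_off':<22}"
                         f"{_fmt(rel, 2):>{width + 12}}"
                         f"  ({self.order[1]}/{self.order[0]})")
        return "\n".join(lines) + "\n"


def build_table1_report(**systems) -> ComparativeReport:
    """Build the comparative report from per-system quantity dicts.

    Each system maps quantity names (tau_off_ns, k_off, tau_on_ns, k_on,
    Kd, dG and their *_sd companions) to numbers.  k_off is derived from
    tau_off via k = 1e9/tau[ns] when absent; the affinity ratio k_off/k_on
    is derived when both rates exist.  Missing quantities are omitted, never
    fabricated.
    """
    if not systems:
        raise ValueError("need at least one system")
    out = {}
    for name, vals in systems.items():
        vals = dict(vals)
        unknown = [k for k in vals
                   if k.removesuffix("_sd") not in
                   {r[0] for r in ROWS}]
        if unknown:
            raise ValueError(f"unknown quantities for {name}: {unknown}")
        if "k_off" not in vals and "tau_off_ns" in vals:
            vals["k_off"] = koff_from_tau(vals["tau_off_ns"])
        if "k_on" not in vals and "tau_on_ns" in vals:
            pass  # k_on needs the effective concentration; never invented
        if ("koff_over_kon" not in vals and "k_off" in vals
                and "k_on" in vals):
            vals["koff_over_kon"] = vals["k_off"] / vals["k_on"]
        out[name] = vals
    return ComparativeReport(systems=out, order=list(systems))
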