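#!/usr/bin/env python
"""Stage 6 — comparative kinetics report.

Assembles the comparative kinetics table of the two model systems from the
metadynamics (stage 2) and MSM (stage 3) results, recomputes the relative
k_off, and renders text + JSON.  Also prints the same report built from the
published kinetic parameters of the real DhaA31/DhaAwt systems, which the
reporting layer consumes as inputs.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from unbindkin import report
from unbindkin import reference_data as ref

OUT = Path(__file__).resolve().parents[1] / "results"


def model_report():
    with open(OUT / "mtd_koff.json") as fh:
        mtd = json.load(fh)
    with open(OUT / "msm_kinetics.json") as fh:
        m = json.load(fh)
    r = report.build_table1_report(
        dhaa31like={"tau_off_ns": mtd["dhaa31like"]["tau_off_ns"],
                    "k_off": mtd["dhaa31like"]["k_off_per_s"],
                    "k_off_sd": mtd["dhaa31like"]["k_off_sd_per_s"]},
        dhaawtlike={"tau_off_ns": mtd["dhaawtlike"]["tau_off_ns"],
                    "k_off": mtd["dhaawtlike"]["k_off_per_s"],
                    "k_off_sd": mtd["dhaawtlike"]["k_off_sd_per_s"]})
    r_msm = report.build_table1_report(
        dhaa31like={"tau_off_ns": m["dhaa31like"]["tau_off_ns"],
                    "tau_on_ns": m["dhaa31like"]["tau_on_ns"],
                    "k_on": m["dhaa31like"]["k_on_per_M_s"],
                    "Kd": m["dhaa31like"]["Kd_M"],
                    "dG": m["dhaa31like"]["dG_kcal"]},
        dhaawtlike={"tau_off_ns": m["dhaawtlike"]["tau_off_ns"],
                    "tau_on_ns": m["dhaawtlike"]["tau_on_ns"],
                    "k_on": m["dhaawtlike"]["k_on_per_M_s"],
                    "Kd": m["dhaawtlike"]["Kd_M"],
                    "dG": m["dhaawtlike"]["dG_kcal"]})
    return r, r_msm


def published_report():
    t31 = ref.TABLE1["DhaA31"]
    twt = ref.TABLE1["DhaAwt"]
    return report.build_table1_report(
        DhaA31={"tau_off_ns": t31["metadynamics"]["tau_off_ns"]},
        DhaAwt={"tau_off_ns": twt["metadynamics"]["tau_off_ns"]})


def main():
    r_mtd, r_msm = model_report()
    text = ("== model systems, infrequent-MTD route ==\n" + r_mtd.to_text()
            + "\n== model systems, MSM route ==\n" + r_msm.to_text()
            + "\n== published transition times, rates recomputed ==\n"
            + published_report().to_text())
    (OUT / "comparative_report.txt").write_text(text)
    with open(OUT / "comparative_report.json", "w") as fh:
        payload = {"mtd": json.loads(r_mtd.to_json()),
                   "msm": json.loads(r_msm.to_json()),
                   "published": json.loads(published_report().to_json())}
        json.dump(payload, fh, indent=2)
    print(text)


if __name__ == "__main__":
    main()
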