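"""Published kinetic parameters for DCP release from DhaA31 and DhaAwt.

These literature-reported dissociation/association transition times, rates
and free energies (from infrequent metadynamics and adaptive-sampling MSM
studies of the two haloalkane dehalogenases, plus stopped-flow experiments)
are inputs to the reporting layer: the package recomputes the derived rows
(k_off from tau_off, relative rates, affinity ratios, stability differences)
from them.
"""

# tau values in ns; rates in s^-1; k_on in M^-1 s^-1; dG in kcal/mol
TABLE1 = {
    "DhaA31": {
        "metadynamics": {"tau_off_ns": 3.5e4, "k_off_printed": 2.8e4},
        "adaptive_ff12SB_TIP3P": {
            "tau_off_ns": 188.0, "k_off_printed": 5.32e6,
            "tau_on_ns": 1.74e3, "k_on_printed": 1.28e8,
            "koff_over_kon_printed": 0.042, "Kd_printed": 0.057,
            "dG_kcal": -1.76,
        },
        "adaptive_ff14SB_TIP3P": {"tau_off_ns": 350.0,
                                  "k_off_printed": 2.86e6},
        "adaptive_ff14SB_OPC3": {"tau_off_ns": 2.2e3,
                                 "k_off_printed": 4.5e5},
    },
    "DhaAwt": {
        "metadynamics": {"tau_off_ns": 9.9e2, "k_off_printed": 1.01e6},
        "adaptive_ff12SB_TIP3P": {
            "tau_off_ns": 75.0, "k_off_printed": 1.33e7, "dG_kcal": -0.54,
        },
        "adaptive_ff14SB_TIP3P": {"tau_off_ns": 73.0,
                                  "k_off_printed": 1.37e7},
        "adaptive_ff14SB_OPC3": {"tau_off_ns": 163.0,
                                 "k_off_printed": 6.2e6},
    },
}

#: stopped-flow conformational-selection rates for DhaAwt + DCP, s^-1
PRE_STEADY_STATE = {"k1": 3.31, "k_minus1": 6.16, "Kd_mM": 0.95}

#: free-energy profile features, kcal/mol and Å (release FES projected on d1)
FES_FEATURES = {
    "DhaA31": {"global_min_A": 5.94, "mouth_min_A": 12.14,
               "barriers_kcal": [4.81]},
    "DhaAwt": {"global_min_A": 5.9, "mouth_min_A": 13.0,
               "barriers_kcal": [2.26, 1.46]},
}

#: hot-spot ordering (most negative ddG_bind first) and TS1 binders
HOTSPOT_ORDER = ["F152", "F168", "F149", "F245"]
TS1_BINDERS = ["F144", "T148", "K175"]
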