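"""Published study anchors used as generator defaults and worked-example inputs.

The long-term trial compares five fertilization regimes in a rice-wheat
rotation: CK (unfertilized control), OPT (optimized NPK), OPTN (+50% N),
OPTP (+50% P), and OPTM (optimized NPK plus straw returning, i.e. an
organic P source).  The constants below are the printed treatment-level
summaries (means +/- standard errors, n = 4 plots) that anchor the
synthetic-data generator and the worked examples.
"""

from __future__ import annotations

TREATMENTS: tuple[str, ...] = ("CK", "OPT", "OPTN", "OPTP", "OPTM")

N_REPLICATES = 4

#: Soil chemical properties: per variable, {treatment: (mean, SE)}.
#: Units: pH unitless; SOM, TN, TP in g kg-1; the rest in mg kg-1.
SOIL_CHEMISTRY: dict[str, dict[str, tuple[float, float]]] = {
    "pH": {
        "CK": (8.01, 0.03), "OPT": (7.75, 0.04), "OPTN": (7.67, 0.05),
        "OPTP": (7.67, 0.11), "OPTM": (7.70, 0.22),
    },
    "SOM": {
        "CK": (22.23, 0.73), "OPT": (26.57, 1.93), "OPTN": (27.45, 2.24),
        "OPTP": (26.92, 1.34), "OPTM": (33.16, 2.35),
    },
    "TN": {
        "CK": (1.23, 0.10), "OPT": (1.42, 0.20), "OPTN": (1.39, 0.03),
        "OPTP": (1.39, 0.10), "OPTM": (1.63, 0.04),
    },
    "TP": {
        "CK": (0.67, 0.02), "OPT": (0.99, 0.05), "OPTN": (1.03, 0.15),
        "OPTP": (1.15, 0.14), "OPTM": (1.09, 0.04),
    },
    "AK": {
        "CK": (82.64, 3.74), "OPT": (86.44, 4.82), "OPTN": (79.72, 8.58),
        "OPTP": (94.32, 23.91), "OPTM": (111.21, 12.84),
    },
    "AP": {
        "CK": (5.77, 5.84), "OPT": (48.69, 8.85), "OPTN": (39.89, 6.07),
        "OPTP": (92.63, 9.03), "OPTM": (62.84, 9.53),
    },
    "AN": {
        "CK": (80.30, 13.34), "OPT": (95.14, 21.95), "OPTN": (97.04, 24.22),
        "OPTP": (111.03, 6.04), "OPTM": (123.03, 19.79),
    },
    "WEOC": {
        "CK": (151.90, 6.54), "OPT": (167.86, 18.05), "OPTN": (164.67, 11.16),
        "OPTP": (157.79, 7.67), "OPTM": (180.74, 7.89),
    },
    "NO3N": {
        "CK": (1.09, 0.07), "OPT": (1.08, 0.05), "OPTN": (1.23, 0.24),
        "OPTP": (1.39, 0.55), "OPTM": (1.33, 0.15),
    },
    "MBC": {
        "CK": (261.89, 75.36), "OPT": (320.22, 65.78), "OPTN": (304.03, 87.39),
        "OPTP": (314.10, 91.94), "OPTM": (307.69, 59.11),
    },
    "MBN": {
        "CK": (17.71, 8.20), "OPT": (38.84, 6.59), "OPTN": (39.30, 11.71),
        "OPTP": (40.28, 9.97), "OPTM": (43.19, 6.24),
    },
    "MBP": {
        "CK": (0.35, 0.11), "OPT": (2.41, 0.48), "OPTN": (2.30, 0.80),
        "OPTP": (0.66, 0.25), "OPTM": (2.05, 0.01),
    },
}

#: Published letter pattern for the AP row (descending-mean roles).
SOIL_CHEMISTRY_LETTERS_AP = {"CK": "d", "OPT": "c", "OPTN": "c", "OPTP": "a", "OPTM": "b"}

# Enzyme activity treatment means (nmol h-1 g-1 dry soil).  The OPTM values
# for BG, CBH and NAG equal the OPT values scaled by the reported contrasts
# (+22.74%, +40.90%, +18.09%).  LAP and ALP decline under every fertilized
# regime, and the implied stoichiometric vector angles span ~22-25 degrees
# with CK highest and OPTP lowest, matching the reported ordering.
ENZYME_MEANS: dict[str, dict[str, float]] = {
    "BG": {"CK": 140.0, "OPT": 180.0, "OPTN": 190.0, "OPTP": 200.0,
           "OPTM": 180.0 * 1.2274},
    "CBH": {"CK": 60.0, "OPT": 75.0, "OPTN": 80.0, "OPTP": 85.0,
            "OPTM": 75.0 * 1.4090},
    "NAG": {"CK": 80.0, "OPT": 94.0, "OPTN": 96.0, "OPTP": 115.0,
            "OPTM": 94.0 * 1.1809},
    "LAP": {"CK": 820.0, "OPT": 800.0, "OPTN": 790.0, "OPTP": 780.0,
            "OPTM": 770.0},
    "ALP": {"CK": 310.0, "OPT": 252.0, "OPTN": 233.0, "OPTP": 189.0,
            "OPTM": 208.0},
}

#: Coefficient of variation used for log-normal enzyme activities.
ENZYME_CV = 0.08

# Bioavailable P fractions (mg kg-1), four parallel extractions.  Values
# encode the reported contrasts: Citrate-P CK 17.70 rising to 31.83 under
# OPTM (+79.82% vs CK, +11.24% vs OPT); Enzyme-P +82.84% (OPTP) and +60.63%
# (OPTM) vs CK with OPTM/OPT = 1.6264; HCl-P +18.90..30.18% vs CK with
# OPTM/OPT = 1.0949.  CaCl2-P is flat across treatments.
P_FRACTION_MEANS: dict[str, dict[str, float]] = {
    "CaCl2_P": {t: 2.50 for t in TREATMENTS},
    "Citrate_P": {"CK": 17.70, "OPT": 31.83 / 1.1124, "OPTN": 27.43,
                  "OPTP": 30.50, "OPTM": 31.83},
    "Enzyme_P": {"CK": 2.330, "OPT": 2.330 * 1.6063 / 1.6264, "OPTN": 2.60,
                 "OPTP": 2.330 * 1.8284, "OPTM": 2.330 * 1.6063},
    "HCl_P": {"CK": 238.02, "OPT": 238.02 * 1.1890, "OPTN": 288.0,
              "OPTP": 300.0, "OPTM": 238.02 * 1.3018},
}

P_FRACTION_CV = 0.10

#: Worked-example endpoints for the Citrate-P contrast (mg kg-1).
CITRATE_P_RANGE = (17.70, 31.83)
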