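"""Bundled treatment-level means from a published barley pot and
incubation study of recycled P fertilizers on an unlimed and a limed
soil.

These are *aggregate* printed values (per-pot raw data were never
deposited) and serve as worked-example inputs: recomputing recoveries,
relative efficiencies, and 1-minute E values from them validates the
formula implementations.  Column meanings match the package-wide unit
conventions (mg P per kg soil, Bq per mg P, percent).
"""

from __future__ import annotations

import pandas as pd

#: soil characterization (mg P per kg dry soil)
SOIL_TOTAL_P = 1024.0
SOIL_ORGANIC_P = 456.0
#: inorganic P basis of the unfertilized soil
SOIL_PI = SOIL_TOTAL_P - SOIL_ORGANIC_P

#: standard fertilizer dose (mg P per kg soil)
DOSE_MG_P_PER_KG = 30.0
#: specific activity of the direct-labeled mineral P control (Bq per mg P)
SA_MINPDIR = 40_000.0
#: soil labeling rate in the pot experiment (Bq per kg soil)
SOIL_LABEL_RATE = 1.1e6
#: solution-to-soil ratio of the exchange-kinetics extraction (L per kg)
SOLUTION_SOIL_RATIO = 10.0
#: exchange-kinetics sampling times (minutes)
KINETICS_TIMES = (1.0, 4.0, 10.0, 30.0, 60.0, 90.0)
#: seed-P input: five-seed dry mass (g) and seed P concentration (mg P/g)
FIVE_SEED_MASS_G = 0.20
SEED_P_CONC_MG_PER_G = 3.49

# treatment means of the pot experiment:
# (soil, treatment, dm g/kg, p_conc mg/g, uptake mg/kg, pdf_fert %, recovery %, rae %)
_POT_ROWS = [
    ("unlimed", "NoP", 3.5, 1.6, 5.7, None, None, None),
    ("unlimed", "MinP", 5.2, 1.9, 10.2, 42.4, 14.4, 100.0),
    ("unlimed", "Manure", 4.1, 1.7, 7.0, 40.2, 8.8, 60.9),
    ("unlimed", "FishSludge", 4.0, 1.9, 7.5, 29.0, 6.9, 47.8),
    ("unlimed", "MeatBoneMeal", 3.5, 1.8, 6.4, 11.2, 2.3, 16.0),
    ("unlimed", "WoodAsh", 3.7, 1.9, 7.1, 23.6, 5.6, 38.7),
    ("unlimed", "MinPdir", 5.0, 2.1, 10.3, 36.9, 12.7, None),
    ("limed", "NoP", 3.5, 1.8, 6.4, None, None, None),
    ("limed", "MinP", 5.0, 2.2, 10.8, 45.1, 16.3, 100.0),
    ("limed", "Manure", 4.6, 1.8, 8.3, 41.0, 10.7, 65.7),
    ("limed", "FishSludge", 4.5, 1.9, 8.7, 28.6, 7.9, 48.6),
    ("limed", "MeatBoneMeal", 3.7, 1.9, 7.0, 18.8, 4.4, 26.9),
    ("limed", "WoodAsh", 3.9, 1.9, 7.6, 28.1, 7.1, 43.8),
    ("limed", "MinPdir", 4.9, 2.3, 11.2, 33.5, 12.5, None),
]

# treatment means of the incubation experiment:
# (soil, treatment, c_p mg/L, m, n, e1min mg/kg, resin d7, resin d21,
#  pdff d7 %, pdff d21 %, pmic d7, pmic d21)
_INCUBATION_ROWS = [
    ("unlimed", "NoP", 0.09, 0.27, 0.40, 3.3, 12.5, 10.1, None, None, 2.8, 6.2),
    ("unlimed", "MinP", 0.15, 0.32, 0.38, 4.8, 21.6, 25.2, 38.0, 52.0, 3.7, 3.6),
    ("unlimed", "Manure", 0.13, 0.29, 0.39, 4.6, 23.7, 13.9, 32.0, 38.0, 6.4, 9.7),
    ("unlimed", "FishSludge", 0.12, 0.27, 0.39, 4.4, 19.1, 16.6, 37.0, 30.0, 5.8, 3.0),
    ("unlimed", "MeatBoneMeal", 0.12, 0.27, 0.39, 4.5, 21.5, 10.1, 25.0, 19.0, None, 9.9),
    ("unlimed", "WoodAsh", 0.12, 0.26, 0.39, 4.4, 19.1, 13.9, 30.0, 40.0, 9.2, 5.0),
    ("limed", "NoP", 0.08, 0.23, 0.37, 3.5, 10.3, 11.8, None, None, 9.1, 6.8),
    ("limed", "MinP", 0.15, 0.27, 0.35, 5.4, 16.7, 23.4, 43.0, 41.0, 18.8, 6.1),
    ("limed", "Manure", 0.13, 0.24, 0.35, 5.3, 18.8, 16.9, 49.0, 40.0, 14.7, 15.1),
    ("limed", "FishSludge", 0.10, 0.24, 0.37, 4.2, 9.7, 13.2, 35.0, 24.0, 14.8, 11.9),
    ("limed", "MeatBoneMeal", 0.09, 0.22, 0.37, 4.2, 12.5, 14.2, 29.0, 12.0, 7.0, 6.7),
    ("limed", "WoodAsh", 0.14, 0.22, 0.34, 6.1, 13.7, 15.5, 40.0, 43.0, 13.1, 9.8),
]

# fertilizer product characterizations:
# (name, total_p g/kg DM, po % of P, h2o % of P, nahco3 % of P,
#  naoh % of P, hcl % of P, organic C g/kg DM)
# The mineral P reference is fully water/NaHCO3-soluble by definition.
_FERTILIZER_ROWS = [
    ("MinP", None, 0.0, 100.0, 0.0, 0.0, 0.0, 0.0),
    ("MinPdir", None, 0.0, 100.0, 0.0, 0.0, 0.0, 0.0),
    ("Manure", 6.0, 24.0, 42.0, 33.0, 4.0, 2.0, 393.0),
    ("FishSludge", 21.0, 14.0, 19.0, 19.0, 12.0, 37.0, 375.0),
    ("MeatBoneMeal", 54.0, 2.0, 4.0, 5.0, 3.0, 88.0, 266.0),
    ("WoodAsh", 17.0, None, None, 43.0, None, 63.0, 0.1),
]


def pot_means() -> pd.DataFrame:
    """Published treatment means of the pot experiment."""
    return pd.DataFrame(
        _POT_ROWS,
        columns=[
            "soil",
            "treatment",
            "dm",
            "p_conc",
            "uptake",
            "pdf_fertilizer_pct",
            "recovery_pct",
            "rae_pct",
        ],
    )


def incubation_means() -> pd.DataFrame:
    """Published treatment means of the incubation experiment."""
    return pd.DataFrame(
        _INCUBATION_ROWS,
        columns=[
            "soil",
            "treatment",
            "c_p",
            "m",
            "n",
            "e1min",
            "resin_p_d7",
            "resin_p_d21",
            "pdff_d7",
            "pdff_d21",
            "pmic_d7",
            "pmic_d21",
        ],
    )


def fertilizer_products() -> pd.DataFrame:
    """Published fertilizer characterizations (sequential Pi fractions)."""
    df = pd.DataFrame(
        _FERTILIZER_ROWS,
        columns=[
            "name",
            "total_p_g_per_kg",
            "po_pct",
            "p_h2o_pct",
            "p_nahco3_pct",
            "p_naoh_pct",
            "p_hcl_pct",
            "org_c_g_per_kg",
        ],
    )
    df["dose"] = DOSE_MG_P_PER_KG
    df["sa_fert"] = df["name"].map({"MinPdir": SA_MINPDIR})
    return df
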