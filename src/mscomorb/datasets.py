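"""Reference tables from the population-based Piedmont (Italy) MS registry
linkage, prevalence date 31 December 2017.

These are the published population characteristics used throughout the
package as inputs: disease counts and group sizes drive the simulator's
default prevalences and odds ratios, and the prevalence arithmetic is
checked against the printed per-1000 figures.

All numbers are as printed; nothing here is computed.
"""

from __future__ import annotations

import pandas as pd

#: Number of persons with MS alive and resident on the prevalence date.
N_PWMS = 8_850

#: Number of MS-free residents (same age range) on the prevalence date.
N_NON_MS = 4_265_864

#: Canonical keys for the 14 autoimmune diseases ascertained from the archives.
AID_DISEASES = (
    "rheumatoid_arthritis",
    "celiac_disease",
    "cidp",
    "type1_diabetes",
    "hashimoto_thyroiditis",
    "hypothyroidism",
    "sle",
    "myasthenia_gravis",
    "psoriatic_arthritis",
    "sarcoidosis",
    "behcet_syndrome",
    "guillain_barre",
    "sjogren_syndrome",
    "ankylosing_spondylitis",
)

#: The nine diseases with GWAS-significant variant panels used for the
#: cumulative comorbidity PRS (MS itself plus eight AIDs; note psoriasis
#: has a panel although the archive algorithm covers psoriatic arthritis).
PRS_DISEASES = (
    "ms",
    "rheumatoid_arthritis",
    "celiac_disease",
    "type1_diabetes",
    "hashimoto_thyroiditis",
    "hypothyroidism",
    "sle",
    "psoriasis",
    "ankylosing_spondylitis",
)

# Per-disease characteristics of the two populations: case counts, % women,
# mean age, mean all-cause hospital discharges in the preceding 5 years.
_CHARACTERISTICS_ROWS = [
    # disease, n_ms, pct_women_ms, age_ms, hosp_ms, n_nonms, pct_women_nonms, age_nonms, hosp_nonms
    ("rheumatoid_arthritis", 54, 85.2, 53.8, 2.9, 20_793, 73.6, 63.3, 1.3),
    ("celiac_disease", 61, 86.9, 43.6, 2.3, 12_802, 72.0, 37.0, 0.7),
    ("cidp", 24, 66.7, 55.8, 4.8, 732, 36.5, 63.5, 3.0),
    ("type1_diabetes", 77, 67.5, 49.3, 3.1, 16_692, 45.0, 53.1, 1.7),
    ("hashimoto_thyroiditis", 236, 90.3, 47.2, 1.9, 54_821, 89.3, 52.9, 0.7),
    ("hypothyroidism", 492, 90.9, 55.5, 2.2, 142_112, 83.4, 64.3, 1.1),
    ("sle", 15, 100.0, 49.6, 3.5, 3_267, 87.3, 55.3, 1.5),
    ("myasthenia_gravis", 10, 80.0, 52.0, 3.5, 1_619, 53.9, 65.4, 1.9),
    ("psoriatic_arthritis", 26, 53.9, 53.6, 2.4, 8_560, 50.6, 58.1, 1.0),
    ("sarcoidosis", 8, 50.0, 46.4, 4.8, 1_648, 52.2, 53.7, 1.6),
    ("behcet_syndrome", 10, 70.0, 39.1, 5.1, 401, 56.1, 45.8, 1.7),
    ("guillain_barre", 14, 64.3, 52.9, 4.1, 1_446, 49.3, 59.6, 2.3),
    ("sjogren_syndrome", 11, 100.0, 58.0, 4.0, 2_662, 93.6, 64.7, 1.4),
    ("ankylosing_spondylitis", 7, 42.9, 48.9, 3.9, 1_977, 42.5, 52.4, 1.1),
]

# Published per-1000 prevalences and covariate-adjusted odds ratios
# (MS-free residents are the reference group).
_ASSOCIATION_ROWS = [
    # disease, prev_ms, prev_nonms, or_age_sex, or_age_sex_hosp
    ("rheumatoid_arthritis", 6.10, 4.87, 1.21, 0.93),
    ("celiac_disease", 6.89, 3.00, 2.29, 2.01),
    ("cidp", 2.71, 0.17, 19.38, 13.53),
    ("type1_diabetes", 8.70, 3.91, 2.32, 1.54),
    ("hashimoto_thyroiditis", 26.67, 12.85, 1.68, 1.61),
    ("hypothyroidism", 55.59, 33.31, 1.59, 1.32),
    ("sle", 1.69, 0.77, 1.80, 1.33),
    ("myasthenia_gravis", 1.13, 0.38, 3.40, 2.43),
    ("psoriatic_arthritis", 2.94, 2.01, 1.51, 1.29),
    ("sarcoidosis", 0.90, 0.39, 2.32, 1.72),
    ("behcet_syndrome", 1.13, 0.09, 11.79, 9.13),
    ("guillain_barre", 1.58, 0.34, 4.93, 3.43),
    ("sjogren_syndrome", 1.24, 0.62, 1.77, 1.36),
    ("ankylosing_spondylitis", 0.79, 0.46, 1.80, 1.48),
]


def population_characteristics() -> pd.DataFrame:
    """Per-disease characteristics of the MS and MS-free populations.

    Columns: case counts, percent women, mean age and mean 5-year
    hospital-discharge counts in each group, indexed by disease key.
    """
    df = pd.DataFrame(
        _CHARACTERISTICS_ROWS,
        columns=[
            "disease",
            "n_ms",
            "pct_women_ms",
            "mean_age_ms",
            "mean_hosp_ms",
            "n_non_ms",
            "pct_women_non_ms",
            "mean_age_non_ms",
            "mean_hosp_non_ms",
        ],
    )
    return df.set_index("disease")


def association_table() -> pd.DataFrame:
    """Published per-1000 prevalences and adjusted odds ratios per disease."""
    df = pd.DataFrame(
        _ASSOCIATION_ROWS,
        columns=[
            "disease",
            "prevalence_ms_per_1000",
            "prevalence_non_ms_per_1000",
            "or_age_sex",
            "or_age_sex_hosp",
        ],
    )
    return df.set_index("disease")


#: Composition of the genotyped MS subset: clinical course counts and the
#: comorbidity split.  19 clinically isolated syndrome, 489 relapsing-
#: remitting, 11 progressive-relapsing, 84 secondary progressive,
#: 34 primary progressive; 65 with at least one autoimmune comorbidity,
#: 572 without.
GENETIC_SUBSET = {
    "clinical_course": {
        "clinically_isolated_syndrome": 19,
        "relapsing_remitting": 489,
        "progressive_relapsing": 11,
        "secondary_progressive": 84,
        "primary_progressive": 34,
    },
    "comorbid": 65,
    "non_comorbid": 572,
    "women": 423,
    "men": 214,
    "population_women": 5_979,
    "population_men": 2_871,
}

#: Published extremes of the non-HLA panel sizes: 23 variants (ankylosing
#: spondylitis) to 201 (MS).
PANEL_SIZE_RANGE = {"ankylosing_spondylitis": 23, "ms": 201}


def genetic_subset_totals() -> dict:
    """Derived totals for the genotyped subset (sums and sex ratios)."""
    gs = GENETIC_SUBSET
    return {
        "n_by_course": sum(gs["clinical_course"].values()),
        "n_by_comorbidity": gs["comorbid"] + gs["non_comorbid"],
        "sex_ratio_subset": gs["women"] / gs["men"],
        "sex_ratio_population": gs["population_women"] / gs["population_men"],
    }
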