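"""Published benchmark values for CT-ventilation functional-avoidance HT
planning.

Group-mean DVH/DFH/NTCP values reported for a 17-patient locally-advanced
lung-cancer cohort (8 RP-risk benefit patients, 9 non-benefit) planned with
Helical TomoTherapy: one anatomical plan and five functional plans sparing
the top 10-50% ventilated lung.  NTCP rows are the grade 2+ radiation
pneumonitis probability of the group-mean fV10 under the probit model
(fV10, m = 0.53, TD50 = 54.1).

These numbers serve as fixed reference inputs for arithmetic
cross-checks (e.g. mean NTCP reductions between strategies) and as
realistic fixtures in examples; the package never claims to re-derive them
from images, which are not public.
"""

from __future__ import annotations

STRATEGIES = ("anatomical", "top10", "top20", "top30", "top40", "top50")

#: Benefit group (n=8): mean values per strategy.
BENEFIT_GROUP_MEANS: dict[str, dict[str, float]] = {
    "NTCP_fV10": {"anatomical": 38.37, "top10": 44.63, "top20": 40.84,
                  "top30": 33.82, "top40": 30.98, "top50": 29.77},
    "fV5":  {"anatomical": 63.94, "top10": 68.19, "top20": 64.21,
             "top30": 57.66, "top40": 54.70, "top50": 52.97},
    "fV10": {"anatomical": 44.69, "top10": 49.77, "top20": 46.45,
             "top30": 40.26, "top40": 37.77, "top50": 36.86},
    "fV20": {"anatomical": 26.41, "top10": 24.84, "top20": 25.21,
             "top30": 24.05, "top40": 23.20, "top50": 23.06},
    "fMLD": {"anatomical": 8.12, "top10": 8.17, "top20": 8.06,
             "top30": 7.64, "top40": 7.55, "top50": 7.44},
    "V5":  {"anatomical": 62.32, "top10": 66.09, "top20": 63.11,
            "top30": 57.76, "top40": 55.15, "top50": 53.51},
    "V10": {"anatomical": 43.24, "top10": 49.87, "top20": 47.60,
            "top30": 41.45, "top40": 38.62, "top50": 37.38},
    "V20": {"anatomical": 24.47, "top10": 24.00, "top20": 24.92,
            "top30": 23.70, "top40": 22.88, "top50": 22.52},
    "MLD": {"anatomical": 13.13, "top10": 13.47, "top20": 13.46,
            "top30": 13.18, "top40": 11.97, "top50": 12.40},
}

#: Non-benefit group (n=9): mean values per strategy.
NON_BENEFIT_GROUP_MEANS: dict[str, dict[str, float]] = {
    "NTCP_fV10": {"anatomical": 20.24, "top10": 26.21, "top20": 26.81,
                  "top30": 23.56, "top40": 22.40, "top50": 21.47},
    "fV5":  {"anatomical": 44.26, "top10": 52.89, "top20": 51.77,
             "top30": 49.96, "top40": 46.18, "top50": 44.84},
    "fV10": {"anatomical": 27.36, "top10": 33.21, "top20": 33.52,
             "top30": 30.89, "top40": 29.77, "top50": 29.00},
    "fV20": {"anatomical": 16.72, "top10": 17.44, "top20": 17.25,
             "top30": 17.09, "top40": 16.53, "top50": 16.49},
    "fMLD": {"anatomical": 5.59, "top10": 6.13, "top20": 6.16,
             "top30": 6.00, "top40": 5.82, "top50": 5.76},
    "V5":  {"anatomical": 41.14, "top10": 48.81, "top20": 47.44,
            "top30": 45.74, "top40": 43.12, "top50": 42.55},
    "V10": {"anatomical": 25.10, "top10": 31.38, "top20": 31.56,
            "top30": 29.75, "top40": 28.15, "top50": 27.26},
    "V20": {"anatomical": 14.48, "top10": 15.05, "top20": 15.63,
            "top30": 15.15, "top40": 14.99, "top50": 14.81},
    "MLD": {"anatomical": 8.52, "top10": 9.41, "top20": 9.54,
            "top30": 9.28, "top40": 9.18, "top50": 9.06},
}

#: PTV/OAR dosimetric means for the benefit group.
BENEFIT_PTV_OAR_MEANS: dict[str, dict[str, float]] = {
    "ptv_V60": {"anatomical": 96.47, "top10": 96.17, "top20": 95.98,
                "top30": 95.98, "top40": 95.67, "top50": 95.65},
    "CI": {"anatomical": 0.85, "top10": 0.86, "top20": 0.85,
           "top30": 0.84, "top40": 0.76, "top50": 0.76},
    "HI": {"anatomical": 0.06, "top10": 0.07, "top20": 0.07,
           "top30": 0.09, "top40": 0.11, "top50": 0.10},
    "heart_Dmean": {"anatomical": 14.71, "top10": 14.56, "top20": 15.21,
                    "top30": 15.96, "top40": 16.74, "top50": 16.99},
    "cord_Dmax": {"anatomical": 32.79, "top10": 32.16, "top20": 33.87,
                  "top30": 37.44, "top40": 40.17, "top50": 40.54},
    "esophagus_Dmean": {"anatomical": 22.97, "top10": 24.08, "top20": 23.88,
                        "top30": 23.22, "top40": 23.70, "top50": 23.49},
}

#: Reported mean +/- SD PTV volumes (cm^3) of the two groups.
PTV_VOLUME_CM3 = {"benefit": (242.39, 103.59), "non_benefit": (121.64, 78.04)}

GROUP_SIZES = {"benefit": 8, "non_benefit": 9}


def mean_reduction(table: dict[str, dict[str, float]], metric: str,
                   strategy: str, reference: str = "anatomical") -> float:
    """Mean reduction of a metric from the reference strategy to another
    (positive = the strategy lowers the metric)."""
    row = table[metric]
    return row[reference] - row[strategy]
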