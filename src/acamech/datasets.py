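"""Bundled reference data: human ACA donor cohort and collagen composition.

Two small tables ship with the package.  The cohort table lists anterior
cerebral artery segments from brain donors stratified by Braak stage
(control / early / intermediate / advanced), with donor age, sex and the
measured unloaded wall thickness and inner/outer diameters; donors may
contribute more than one segment.  The collagen table gives the group-level
percentage of total collagen abundance (mean and sample SD) for each
collagen type quantified by label-free proteomics in the control and
advanced-AD groups.
"""

from __future__ import annotations

import pandas as pd

# (group, donor_id, age, sex, braak_stage, thickness_mm, inner_d_mm, outer_d_mm)
_COHORT_ROWS = [
    ("early", "E1", 66, "M", "early", 0.35, 2.09, 2.79),
    ("early", "E1", 66, "M", "early", 0.25, 2.00, 2.50),
    ("early", "E2", 61, "F", "early", 0.21, 1.63, 2.05),
    ("early", "E2", 61, "F", "early", 0.27, 1.69, 2.22),
    ("early", "E3", 80, "F", "II-III", 0.24, 1.52, 2.00),
    ("early", "E4", 72, "M", "II-III", 0.31, 1.85, 2.46),
    ("intermediate", "I1", 77, "F", "III-IV", 0.22, 1.49, 1.92),
    ("intermediate", "I2", 79, "F", "III-IV", 0.32, 2.07, 2.72),
    ("intermediate", "I3", 69, "M", "IV", 0.33, 1.87, 2.54),
    ("intermediate", "I3", 69, "M", "IV", 0.34, 1.78, 2.47),
    ("advanced", "A1", 63, "M", "V", 0.35, 1.89, 2.59),
    ("advanced", "A2", 78, "F", "V", 0.24, 1.88, 2.35),
    ("advanced", "A2", 78, "F", "V", 0.22, 1.49, 1.93),
    ("advanced", "A3", 61, "M", "V", 0.28, 1.92, 2.48),
    ("advanced", "A3", 61, "M", "V", 0.24, 1.87, 2.35),
    ("advanced", "A4", 62, "M", "VI", 0.25, 1.90, 2.40),
    ("advanced", "A5", 63, "F", "advanced", 0.31, 1.77, 2.38),
    ("advanced", "A6", 95, "F", "advanced", 0.39, 1.90, 2.68),
    ("advanced", "A7", 83, "M", "V", 0.32, 2.07, 2.70),
    ("advanced", "A8", 79, "M", "advanced", 0.30, 1.98, 2.57),
    ("control", "C1", 59, "F", "-", 0.27, 1.85, 2.40),
    ("control", "C1", 59, "F", "-", 0.33, 1.83, 2.50),
    ("control", "C2", 72, "F", "-", 0.28, 1.63, 2.20),
    ("control", "C2", 72, "F", "-", 0.29, 2.26, 2.84),
    ("control", "C3", 83, "M", "-", 0.35, 2.07, 2.78),
    ("control", "C3", 83, "M", "-", 0.33, 2.07, 2.70),
    ("control", "C4", 72, "M", "-", 0.31, 2.00, 2.61),
    ("control", "C4", 72, "M", "-", 0.31, 2.11, 2.73),
]

# collagen type -> (control mean %, control SD, advanced-AD mean %, AD SD)
_COLLAGEN_ROWS = {
    "I": (43.52, 16.42, 54.14, 17.38),
    "II": (0.26, 0.08, 0.33, 0.17),
    "III": (26.98, 4.43, 24.10, 4.35),
    "IV": (23.11, 10.47, 16.32, 15.59),
    "V": (0.07, 0.01, 0.10, 0.03),
    "VI": (4.52, 1.77, 3.51, 3.02),
    "VIII": (0.76, 0.30, 0.81, 0.58),
    "XII": (0.01, 0.00, 0.02, 0.02),
    "XIV": (0.20, 0.10, 0.10, 0.09),
    "XVI": (0.22, 0.05, 0.24, 0.15),
    "XVIII": (0.30, 0.14, 0.30, 0.26),
    "XXI": (0.03, 0.01, 0.04, 0.03),
}

#: Group-level empty-band statistics: media/adventitia mean and SD area
#: fractions measured on the binarized elastin projections.
MEDIA_AREA_FRACTION = (0.318, 0.085)
ADVENTITIA_AREA_FRACTION = (0.478, 0.164)


def aca_cohort_table() -> pd.DataFrame:
    """Per-segment cohort records (one row per tested ACA segment)."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "group", "donor_id", "age", "sex", "braak_stage",
            "thickness_mm", "inner_diameter_mm", "outer_diameter_mm",
        ],
    )


def collagen_composition() -> pd.DataFrame:
    """Group-level collagen composition (% of total collagen, mean and SD)."""
    rows = [
        {"collagen_type": k, "control_mean": v[0], "control_sd": v[1],
         "ad_mean": v[2], "ad_sd": v[3]}
        for k, v in _COLLAGEN_ROWS.items()
    ]
    return pd.DataFrame(rows)
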