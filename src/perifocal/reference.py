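"""Published summary statistics of a 32-patient AMTL reference cohort.

A published series of 32 anteromedial temporal lobectomy (AMTL) patients
with mesial temporal sclerosis, analysed with the same voxel-based method
this package implements, serves as the reference for report layouts and
for arithmetic-consistency checks: its printed subgroup means obey the
additivity ``pre - resected = post`` and its printed subgroup differences
equal the difference of the printed means, both up to printed rounding.
The patient-level imaging behind these summaries is not public, so they
are inputs (printed numbers), not outputs, of this package.

Volumes are mm³, percentages are %, all printed to the precision shown in
the source tables.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "engel_outcome_counts",
    "pre_post_summary",
    "subgroup_comparison_summary",
]


def engel_outcome_counts() -> pd.Series:
    """Engel class counts at the 2-year follow-up of the reference cohort."""
    return pd.Series({"I": 25, "II": 1, "III": 2, "IV": 4}, name="n_patients")


def pre_post_summary() -> pd.DataFrame:
    """Printed subgroup means of pre-surgical, resected and post-resection
    perifocal abnormality volumes (mm³), per tracer and VOI.

    ``outcome`` is the dichotomized Engel subgroup; SDs are printed values.
    """
    rows = [
        # voi, tracer, outcome, n, pre(SD), resected(SD), post(SD)
        ("ahph", "FDG", "satisfactory", 25, 3221, 1537, 712, 1053, 2509, 868),
        ("ahph", "FDG", "unsatisfactory", 7, 3007, 1344, 521, 367, 2486, 1114),
        ("ahph", "FMZ", "satisfactory", 25, 3101, 617, 428, 435, 2673, 574),
        ("ahph", "FMZ", "unsatisfactory", 7, 2685, 691, 447, 369, 2238, 585),
        ("tl", "FDG", "satisfactory", 25, 33358, 7224, 14461, 4751, 18896, 5670),
        ("tl", "FDG", "unsatisfactory", 7, 27460, 4738, 12518, 4848, 14942, 3761),
        ("tl", "FMZ", "satisfactory", 25, 25469, 6175, 9203, 3225, 16266, 4966),
        ("tl", "FMZ", "unsatisfactory", 7, 22609, 3985, 8952, 3575, 13657, 3475),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "voi", "tracer", "outcome", "n",
            "pre_mean_mm3", "pre_sd_mm3",
            "resected_mean_mm3", "resected_sd_mm3",
            "post_mean_mm3", "post_sd_mm3",
        ],
    )


def subgroup_comparison_summary() -> pd.DataFrame:
    """Printed satisfactory vs unsatisfactory subgroup means and their
    printed difference for every volumetric variable, per VOI.

    Units are mm³ for volumes and percentage points for the two percentage
    variables.
    """
    rows = [
        # voi, variable, satisfactory mean, unsatisfactory mean, printed difference
        ("ahph", "FDG pre-surgical volume", 3221, 3007, 214),
        ("ahph", "FDG resected volume", 712, 521, 191),
        ("ahph", "FDG percentage of non-resected abnormality", 82, 81, 1),
        ("ahph", "FMZ pre-surgical volume", 3101, 2685, 416),
        ("ahph", "FMZ resected volume", 428, 447, -19),
        ("ahph", "FMZ percentage of non-resected abnormality", 87, 84, 3),
        ("ahph", "MRI-derived volume resected", 1572, 1509, 63),
        ("ahph", "MRI percentage of resected volume", 19, 20, -2),
        ("tl", "FDG pre-surgical volume", 33358, 27460, 5898),
        ("tl", "FDG resected volume", 14462, 12518, 1943),
        ("tl", "FDG percentage of non-resected abnormality", 57, 55, 2),
        ("tl", "FMZ pre-surgical volume", 25469, 22610, 2859),
        ("tl", "FMZ resected volume", 9203, 8953, 250),
        ("tl", "FMZ percentage of non-resected abnormality", 64, 61, 3),
        ("tl", "MRI-derived volume resected", 19647, 17997, 1650),
        ("tl", "MRI percentage of resected volume", 27, 27, 0),
    ]
    return pd.DataFrame(
        rows,
        columns=["voi", "variable", "satisfactory_mean", "unsatisfactory_mean",
                 "printed_difference"],
    )
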