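"""Printed summary counts of the published 159-patient clinical cohort.

The original study cohort's MRI data are not publicly deposited; what is
available are the printed summary tables. These counts are kept here as
reference *inputs* so that the table-formatting arithmetic (integer
percentages of group-specific totals, cohort-flow counts) can be recomputed
and checked against the printed values. The internal inconsistencies of the
printed tables (e.g. 113 vs 114 IDH-mutated, group sizes 50/64/45 vs
49/65/45 between figures and tables) are preserved as printed and not
adjudicated here.
"""

from __future__ import annotations

from .cohort_analysis import _pct

__all__ = [
    "TOTAL_PATIENTS",
    "GROUP_SIZES_FIGURE",
    "GROUP_SIZES_REGION_TABLE",
    "CONTACT_COUNTS",
    "REGION_COUNTS",
    "FRONTAL_TOTAL",
    "FRONTAL_IDH_MUTATED",
    "TEMPORAL_TOTAL",
    "recompute_printed_percentages",
]

TOTAL_PATIENTS = 159
# screened cohort flow: 205 eligible, minus exclusions
SCREENED_PATIENTS = 205
EXCLUDED = {"missing_mri": 39, "no_tissue": 6, "diagnosis_revised": 1}

GROUP_SIZES_FIGURE = {  # heatmap figure caption
    "oligodendroglioma_IDHmut_codel": 50,
    "astrocytoma_IDHmut": 64,
    "astrocytoma_IDHwt": 45,
}
GROUP_SIZES_REGION_TABLE = {  # region-distribution table headers
    "oligodendroglioma_IDHmut_codel": 49,
    "astrocytoma_IDHmut": 65,
    "astrocytoma_IDHwt": 45,
}

CONTACT_COUNTS = {"svz": 108, "sgz": 72, "both": 70, "neither": 48}

# region-distribution table: counts per region per group
REGION_COUNTS = {
    "frontal": {"oligodendroglioma_IDHmut_codel": 31, "astrocytoma_IDHmut": 38, "astrocytoma_IDHwt": 15},
    "parietal": {"oligodendroglioma_IDHmut_codel": 7, "astrocytoma_IDHmut": 7, "astrocytoma_IDHwt": 5},
    "temporal": {"oligodendroglioma_IDHmut_codel": 7, "astrocytoma_IDHmut": 13, "astrocytoma_IDHwt": 15},
    "deep_central": {"oligodendroglioma_IDHmut_codel": 4, "astrocytoma_IDHmut": 7, "astrocytoma_IDHwt": 9},
    "brainstem_cerebellum": {"oligodendroglioma_IDHmut_codel": 0, "astrocytoma_IDHmut": 0, "astrocytoma_IDHwt": 1},
}

FRONTAL_TOTAL = 84  # frontal lesions of 159
FRONTAL_IDH_MUTATED = 69  # IDH-mutated among the frontal lesions
TEMPORAL_TOTAL = 35


def recompute_printed_percentages() -> dict[str, int]:
    """Re-derive every printed percentage from the printed counts.

    Returns integer percentages (rounded half-up) keyed by what they
    describe, e.g. the frontal share of the whole cohort or the frontal
    share within the oligodendroglioma group.
    """
    out = {
        "cohort_n": TOTAL_PATIENTS,
        "cohort_flow_n": SCREENED_PATIENTS - sum(EXCLUDED.values()),
        "frontal_pct_of_cohort": _pct(FRONTAL_TOTAL, TOTAL_PATIENTS),
        "frontal_idh_mutated_pct": _pct(FRONTAL_IDH_MUTATED, FRONTAL_TOTAL),
        "temporal_pct_of_cohort": _pct(TEMPORAL_TOTAL, TOTAL_PATIENTS),
        "contact_svz_pct": _pct(CONTACT_COUNTS["svz"], TOTAL_PATIENTS),
        "contact_sgz_pct": _pct(CONTACT_COUNTS["sgz"], TOTAL_PATIENTS),
        "contact_both_pct": _pct(CONTACT_COUNTS["both"], TOTAL_PATIENTS),
        "contact_neither_pct": _pct(CONTACT_COUNTS["neither"], TOTAL_PATIENTS),
    }
    for region, per_group in REGION_COUNTS.items():
        for group, count in per_group.items():
            total = GROUP_SIZES_REGION_TABLE[group]
            out[f"{region}_pct_{group}"] = _pct(count, total)
    return out
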