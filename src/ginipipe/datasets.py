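"""Published carrier-count inputs for the MAGEC1 start-codon variant.

These are the study's genotyped group sizes and carrier counts for the
p.Met1? (c.2T>C) variant: hereditary-prostate-cancer (HPC) probands,
unselected prostate-cancer (PC) cases, and four control groups (male and
female blood donors, benign-prostate-hyperplasia patients, and low-PSA
screening controls).  They are inputs to the association stage, which
recomputes odds ratios and intervals from them.
"""

from __future__ import annotations

import pandas as pd

# group, carriers, total, role
CARRIER_COUNTS: tuple[tuple[str, int, int, str], ...] = (
    ("male_blood_donors", 7, 757, "control"),
    ("female_blood_donors", 5, 764, "control"),
    ("bph_patients", 2, 375, "control"),
    ("psa_controls", 9, 746, "control"),
    ("unselected_pc", 13, 757, "case"),
    ("hpc_probands", 4, 163, "case"),
)

# The study reports each case group against two control pools: the three
# blood-donor/BPH groups, and all four groups including the PSA controls.
CONTROL_POOLS: dict[str, tuple[str, ...]] = {
    "donors_bph": ("male_blood_donors", "female_blood_donors", "bph_patients"),
    "all_controls": (
        "male_blood_donors",
        "female_blood_donors",
        "bph_patients",
        "psa_controls",
    ),
}


def carrier_count_table() -> pd.DataFrame:
    """Carrier counts as a tidy frame (group, carriers, total, role)."""
    return pd.DataFrame(
        list(CARRIER_COUNTS), columns=["group", "carriers", "total", "role"]
    )
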