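"""Cohort table schema and I/O.

A cohort is a pandas DataFrame with one row per eye.  Flags are encoded
0/1; missing values are empty in CSV.  Baseline OCTA metrics use the bare
column names (``vpd_scp``, ``lac_dcp``...) because they are the tree
predictors; 12-month values carry the ``_m12`` suffix.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ID_COLUMNS = ["eye_id", "patient_id"]

CONTINUOUS_COLUMNS = [
    "hba1c",
    "bcva_baseline",
    "bcva_final",
    "cmt_baseline",
    "cmt_final",
    "vpd_scp",
    "vpd_dcp",
    "lac_scp",
    "lac_dcp",
    "vpd_scp_m12",
    "vpd_dcp_m12",
    "lac_scp_m12",
    "lac_dcp_m12",
    "n_injections",
]

FLAG_COLUMNS = [
    "vma",
    "macular_cysts",
    "subretinal_fluid",
    "hard_exudates",
    "ez_alteration",
    "macular_cysts_m12",
    "subretinal_fluid_m12",
    "hard_exudates_m12",
    "ez_alteration_m12",
    "microaneurysms",
    "irma",
    "neovascularization",
]

# (baseline flag, 12-month flag) pairs for paired-change testing
PAIRED_FLAGS = [
    ("macular_cysts", "macular_cysts_m12"),
    ("subretinal_fluid", "subretinal_fluid_m12"),
    ("hard_exudates", "hard_exudates_m12"),
    ("ez_alteration", "ez_alteration_m12"),
]

# (baseline, 12-month) continuous pairs, mirroring the summary-report rows
PAIRED_CONTINUOUS = [
    ("bcva_baseline", "bcva_final"),
    ("cmt_baseline", "cmt_final"),
    ("vpd_scp", "vpd_scp_m12"),
    ("lac_scp", "lac_scp_m12"),
    ("vpd_dcp", "vpd_dcp_m12"),
    ("lac_dcp", "lac_dcp_m12"),
]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check range invariants; returns the table for chaining."""
    if len(table) == 0:
        raise ValueError("empty cohort table")
    for col in ("bcva_baseline", "bcva_final"):
        if col in table and not table[col].dropna().between(0, 100).all():
            raise ValueError(f"{col} outside [0, 100] ETDRS letters")
    for col in ("cmt_baseline", "cmt_final"):
        if col in table and not (table[col].dropna() > 0).all():
            raise ValueError(f"{col} must be positive (micrometres)")
    for col in ("vpd_scp", "vpd_dcp", "vpd_scp_m12", "vpd_dcp_m12"):
        if col in table and not table[col].dropna().between(0, 1).all():
            raise ValueError(f"{col} outside [0, 1]")
    for col in ("lac_scp", "lac_dcp", "lac_scp_m12", "lac_dcp_m12"):
        if col in table and not (table[col].dropna() >= 0).all():
            raise ValueError(f"{col} must be non-negative")
    for col in FLAG_COLUMNS:
        if col in table and not table[col].dropna().isin([0, 1]).all():
            raise ValueError(f"flag column {col} must be 0/1")
    return table


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_reference_cohort() -> pd.DataFrame:
    """Packaged 66-eye pseudo-cohort with the study's published margins.

    Synthetic stand-in for the (undeposited) clinical table: every
    published marginal count is reproduced exactly — baseline FA flags
    (48 microaneurysms, 49 IRMA, 22 neovascularization out of 66),
    SD-OCT flags at baseline (63 cysts, 16 subretinal fluid, 22 hard
    exudates, 45 EZ alterations) and at 12 months (31, 4, 9, 29), and
    the outcome-tree strata: 36 eyes with CMT >= 373 µm, of which 10
    with DCP LAC >= 0.41 (final BCVA 65 letters) and 26 with DCP
    LAC < 0.41 (final BCVA 73 letters).  Individual rows are synthetic.
    """
    ref = resources.files("octadme.data") / "synthetic_reference_cohort.csv"
    try:
        with resources.as_file(ref) as path:
            table = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise FileNotFoundError("packaged reference cohort asset missing") from exc
    if len(table) != 66:
        raise ValueError(f"reference cohort corrupt: expected 66 rows, got {len(table)}")
    return validate_cohort(table)
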