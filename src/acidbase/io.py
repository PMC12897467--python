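"""Cohort CSV reading and writing.

The canonical on-disk cohort format is a plain CSV with one header row and
columns ``ph, paco2_mmhg, hco3_mmol_l, sbe_mmol_l, na, k, cl, ca, mg,
lactate, albumin_g_l, pi_mmol_l``. Missing cells are empty strings; rows
with any missing required field are dropped (complete-case analysis — no
imputation is ever applied).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .chem import PatientChemistry

COHORT_COLUMNS = [
    "ph",
    "paco2_mmhg",
    "hco3_mmol_l",
    "sbe_mmol_l",
    "na",
    "k",
    "cl",
    "ca",
    "mg",
    "lactate",
    "albumin_g_l",
    "pi_mmol_l",
]

# Albumin below this is far outside the g/L range seen even in severe
# hypoalbuminemia and almost certainly means the file carries g/dL.
_ALBUMIN_G_L_FLOOR = 10.0


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, applying complete-case filtering and unit guards.

    Raises ``ValueError`` if required columns are absent or if any albumin
    value is below 10 (plausible g/dL input; this package uses g/L
    everywhere).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    df = df.dropna(subset=COHORT_COLUMNS).reset_index(drop=True)
    if (df["albumin_g_l"] < _ALBUMIN_G_L_FLOOR).any():
        raise ValueError(
            "albumin_g_l below 10 — values look like g/dL; convert to g/L"
        )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table in the canonical column order."""
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    df[COHORT_COLUMNS + extra].to_csv(path, index=False)


def row_to_patient(row) -> PatientChemistry:
    """Build a validated :class:`PatientChemistry` from one cohort row."""
    return PatientChemistry(
        ph=float(row["ph"]),
        paco2=float(row["paco2_mmhg"]),
        hco3=float(row["hco3_mmol_l"]),
        sbe=float(row["sbe_mmol_l"]),
        na=float(row["na"]),
        k=float(row["k"]),
        cl=float(row["cl"]),
        ca=float(row["ca"]),
        mg=float(row["mg"]),
        lactate=float(row["lactate"]),
        albumin=float(row["albumin_g_l"]),
        pi=float(row["pi_mmol_l"]),
    )
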