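"""Chlorophyll quantification and sequential-elution Cu bookkeeping.

Chlorophyll a and b concentrations (ug/mL) follow from DMF-extract
absorbances at 663.8 nm and 646.8 nm via the standard spectrophotometric
equations:

    Chl a   = 12.00 * E663.8 - 3.11 * E646.8
    Chl b   = 20.78 * E646.8 - 4.88 * E663.8
    Chl a+b = 17.67 * E646.8 + 7.12 * E663.8

The combined coefficients are exactly the sums of the individual ones
(7.12 = 12.00 - 4.88, 17.67 = 20.78 - 3.11), so Chl a+b == Chl a + Chl b
identically.  Concentrations are then adjusted per mg wet weight of the
2-cm frond tip, and the a/b ratio (weight-invariant) is reported.

The sequential elution technique (SET) washes frond pairs through DI
water, EDTA, and nitric acid, separating surface-bound, extracellular and
intracellular Cu.  The three ICP-MS fractions (nmol) are totalled and
normalized by wet and dry weight; the dry-weight content is also expressed
in mg/kg via the molar mass of Cu.

This module also ships verbatim transcriptions of the study's chemistry
tables as packaged CSVs: 120 chlorophyll records and 105 SET records.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

# Spectrophotometric coefficients (ug/mL per absorbance unit).
CHL_A_COEF = (12.00, -3.11)   # (E663.8, E646.8)
CHL_B_COEF = (-4.88, 20.78)
CHL_TOTAL_COEF = (7.12, 17.67)

#: Molar mass of Cu, g/mol, for nmol/g <-> mg/kg conversion.
CU_MOLAR_MASS = 63.546

#: Expected fixture row counts from the experiment design.
N_CHLOROPHYLL_RECORDS = 120   # 3 trays x 10 fronds x 4 samplings
N_SET_RECORDS = 105           # 3 trays x (5 controls + 3 x 10 post-dose)
N_SET_CONTROLS = 15


class ChemistryValidationError(ValueError):
    """Raised on physically impossible inputs or malformed fixtures."""


def chl_a(e663_8: float, e646_8: float) -> float:
    """Chlorophyll-a concentration, ug/mL."""
    return CHL_A_COEF[0] * e663_8 + CHL_A_COEF[1] * e646_8


def chl_b(e663_8: float, e646_8: float) -> float:
    """Chlorophyll-b concentration, ug/mL."""
    return CHL_B_COEF[0] * e663_8 + CHL_B_COEF[1] * e646_8


def chl_total(e663_8: float, e646_8: float) -> float:
    """Total chlorophyll a+b, ug/mL; identically chl_a + chl_b."""
    return CHL_TOTAL_COEF[0] * e663_8 + CHL_TOTAL_COEF[1] * e646_8


@dataclass
class ChlorophyllMeasurement:
    """One frond's spectrophotometric record with derived quantities."""

    e663_8: float
    e646_8: float
    wet_weight_mg: float
    chl_a_ug_ml: float
    chl_b_ug_ml: float
    chl_total_ug_ml: float
    chl_a_per_mg: float
    chl_b_per_mg: float
    total_per_mg: float
    ab_ratio: float | None
    below_detection: bool


def per_weight(e663_8: float, e646_8: float, wet_weight_mg: float) -> ChlorophyllMeasurement:
    """Quantify chlorophyll and adjust per mg wet weight.

    Negative concentrations (absorbance noise near the detection limit)
    are kept but flagged, never clamped.  The a/b ratio is undefined
    (None) when chl_b <= 0.
    """
    if wet_weight_mg <= 0:
        raise ChemistryValidationError("wet weight must be positive")
    a = chl_a(e663_8, e646_8)
    b = chl_b(e663_8, e646_8)
    tot = chl_total(e663_8, e646_8)
    return ChlorophyllMeasurement(
        e663_8=e663_8,
        e646_8=e646_8,
        wet_weight_mg=wet_weight_mg,
        chl_a_ug_ml=a,
        chl_b_ug_ml=b,
        chl_total_ug_ml=tot,
        chl_a_per_mg=a / wet_weight_mg,
        chl_b_per_mg=b / wet_weight_mg,
        total_per_mg=tot / wet_weight_mg,
        ab_ratio=(a / b) if b > 0 else None,
        below_detection=a < 0 or b < 0,
    )


@dataclass
class SETMeasurement:
    """Cu recovered from one frond pair across the three elution fractions."""

    wet_weight_g: float
    dry_weight_g: float
    cu_di_nmol: float
    cu_edta_nmol: float
    cu_hno3_nmol: float
    cu_total_nmol: float
    cu_ww_nmol_per_g: float
    cu_dw_nmol_per_g: float
    cu_dw_mg_per_kg: float
    weight_warning: bool


def nmol_per_g_to_mg_per_kg(c: float) -> float:
    """nmol Cu per g tissue -> mg Cu per kg tissue (x 63.546e-3)."""
    return c * CU_MOLAR_MASS * 1e-3


def cu_content(
    cu_di_nmol: float,
    cu_edta_nmol: float,
    cu_hno3_nmol: float,
    wet_weight_g: float,
    dry_weight_g: float,
) -> SETMeasurement:
    """Total the elution fractions and normalize by wet and dry weight."""
    if wet_weight_g <= 0 or dry_weight_g <= 0:
        raise ChemistryValidationError("weights must be positive")
    for frac in (cu_di_nmol, cu_edta_nmol, cu_hno3_nmol):
        if frac < 0:
            raise ChemistryValidationError("fraction amounts must be >= 0")
    total = cu_di_nmol + cu_edta_nmol + cu_hno3_nmol
    dw = total / dry_weight_g
    return SETMeasurement(
        wet_weight_g=wet_weight_g,
        dry_weight_g=dry_weight_g,
        cu_di_nmol=cu_di_nmol,
        cu_edta_nmol=cu_edta_nmol,
        cu_hno3_nmol=cu_hno3_nmol,
        cu_total_nmol=total,
        cu_ww_nmol_per_g=total / wet_weight_g,
        cu_dw_nmol_per_g=dw,
        cu_dw_mg_per_kg=nmol_per_g_to_mg_per_kg(dw),
        weight_warning=dry_weight_g > wet_weight_g,
    )


def _data_path(name: str) -> Path:
    return Path(resources.files("mosslif").joinpath("data", name))


def load_chlorophyll_table(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged chlorophyll-extraction table: 120 per-mg adjusted records.

    Carries the printed a/b ratio column verbatim alongside a recomputed
    chl_a_per_mg / chl_b_per_mg ratio; the two disagree for most rows in
    the source and neither is silently preferred.
    """
    df = pd.read_csv(path or _data_path("table1_chlorophyll.csv"))
    if len(df) != N_CHLOROPHYLL_RECORDS:
        raise ChemistryValidationError(
            f"expected {N_CHLOROPHYLL_RECORDS} chlorophyll records, got {len(df)}"
        )
    required = {"tray", "sample", "chl_a_per_mg", "chl_b_per_mg",
                "total_per_mg", "ab_ratio_printed"}
    if not required.issubset(df.columns):
        raise ChemistryValidationError("chlorophyll table missing columns")
    df["ab_ratio_recomputed"] = df["chl_a_per_mg"] / df["chl_b_per_mg"]
    return df


def load_set_table(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged SET Cu table: 105 frond-pair records (15 controls).

    ``cu_ww`` and ``cu_dw`` are stored exactly as printed; the source
    labels the table in both nmol/g and mg/kg without attributing a unit
    per column, so unit interpretation stays with the caller.
    """
    df = pd.read_csv(path or _data_path("table2_set_cu.csv"))
    if len(df) != N_SET_RECORDS:
        raise ChemistryValidationError(
            f"expected {N_SET_RECORDS} SET records, got {len(df)}"
        )
    if not {"tray", "sample", "cu_ww", "cu_dw"}.issubset(df.columns):
        raise ChemistryValidationError("SET table missing columns")
    n_controls = int(df["sample"].str.startswith("Control").sum())
    if n_controls != N_SET_CONTROLS:
        raise ChemistryValidationError(
            f"expected {N_SET_CONTROLS} SET controls, got {n_controls}"
        )
    df["is_control"] = df["sample"].str.startswith("Control")
    return df


def load_acquisition_table(path: str | Path | None = None) -> pd.DataFrame:
    """The nine laser/filter acquisition combinations (metadata labels)."""
    df = pd.read_csv(path or _data_path("table3_acquisitions.csv"))
    if len(df) != 9:
        raise ChemistryValidationError("expected 9 acquisition combinations")
    return df


def load_chemistry_tables(
    table1: str | Path | None = None, table2: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate both chemistry tables."""
    return load_chlorophyll_table(table1), load_set_table(table2)
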