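"""Published summary values from the mouse xenograft study this package models.

The in-vivo raw data of the study — an IgG4–interferon-alpha fusion protein
given as a single i.v. bolus at 1 and 10 mg/kg to LP-1 xenograft mice, with
plasma and tumor measured by three assay platforms — were published only as
summary figures and tables. The printed summary values are reproduced here
as package constants so the analysis layers (exposure ratios, cross-assay
comparison, QC reproduction) can run against the real study numbers.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "assay_qualification_table",
    "exposure_summary_table",
    "EXPOSURE_SUMMARY",
    "QC_QUALIFICATION",
]

# Intra-assay qualification: platform, signature peptide, matrix, QC level,
# nominal conc, mean back-calculated conc, %CV, %RE (as printed, one decimal).
_QC_ROWS = [
    ("LBA", "-", "plasma", "LQC", 3.00, 2.79, 8.1, -7.0),
    ("LBA", "-", "plasma", "MQC", 30.0, 32.3, 12.1, 7.6),
    ("LBA", "-", "plasma", "HQC", 240.0, 278.0, 12.9, 15.6),
    ("LBA", "-", "tumor", "LQC", 0.300, 0.301, 8.0, 0.3),
    ("LBA", "-", "tumor", "MQC", 2.00, 2.14, 5.7, 7.0),
    ("LBA", "-", "tumor", "HQC", 8.00, 8.27, 4.1, 3.3),
    ("IC-LC/MS", "IgG4", "plasma", "LQC", 0.300, 0.353, 4.1, 17.7),
    ("IC-LC/MS", "IgG4", "plasma", "MQC", 2.00, 2.20, 7.6, 10.0),
    ("IC-LC/MS", "IgG4", "plasma", "HQC", 80.0, 85.2, 2.7, 6.5),
    ("IC-LC/MS", "IgG4", "tumor", "LQC", 0.300, 0.316, 8.2, 5.2),
    ("IC-LC/MS", "IgG4", "tumor", "MQC", 2.00, 1.98, 2.3, -0.8),
    ("IC-LC/MS", "IFNalpha", "plasma", "LQC", 0.300, 0.334, 10.2, 11.2),
    ("IC-LC/MS", "IFNalpha", "plasma", "MQC", 2.00, 2.18, 5.4, 9.1),
    ("IC-LC/MS", "IFNalpha", "plasma", "HQC", 80.0, 88.1, 4.1, 10.1),
    ("IC-LC/MS", "IFNalpha", "tumor", "LQC", 0.300, 0.329, 15.4, 9.5),
    ("IC-LC/MS", "IFNalpha", "tumor", "MQC", 2.00, 1.67, 6.7, -16.6),
]

QC_QUALIFICATION = pd.DataFrame(
    _QC_ROWS,
    columns=["platform", "peptide", "matrix", "level", "nominal",
             "mean_conc", "cv_percent", "re_percent"],
)

# Non-compartmental exposure summary per matrix, dose and assay:
# AUC (h·μg/mL), CL (mL/h/kg, plasma only), Cmax (μg/mL), T1/2 (h, plasma,
# printed once per dose without assay attribution).
_EXPOSURE_ROWS = [
    # matrix, dose mg/kg, assay, auc, cl, cmax, t_half
    ("plasma", 1, "LBA", 1470.0, 0.624, 17.3, 98.1),
    ("plasma", 1, "ICMS_IFNA", 1600.0, 0.539, 17.3, None),
    ("plasma", 1, "ICMS_IGG4", 1650.0, 0.527, 17.6, None),
    ("plasma", 10, "LBA", 16200.0, 0.559, 194.0, 90.8),
    ("plasma", 10, "ICMS_IFNA", 16000.0, 0.593, 202.0, None),
    ("plasma", 10, "ICMS_IGG4", 16400.0, 0.568, 194.0, None),
    ("tumor", 1, "LBA", 229.0, None, 2.31, None),
    ("tumor", 1, "ICMS_IFNA", 227.0, None, 1.93, None),
    ("tumor", 1, "ICMS_IGG4", 168.0, None, 1.57, None),
    ("tumor", 10, "LBA", 2210.0, None, 14.0, None),
    ("tumor", 10, "ICMS_IFNA", 1730.0, None, 10.9, None),
    ("tumor", 10, "ICMS_IGG4", 1480.0, None, 8.67, None),
]

EXPOSURE_SUMMARY = pd.DataFrame(
    _EXPOSURE_ROWS,
    columns=["matrix", "dose_mg_kg", "assay", "auc", "cl_per_kg", "cmax", "t_half"],
)


def assay_qualification_table() -> pd.DataFrame:
    """Printed intra-assay precision/accuracy table (copy)."""
    return QC_QUALIFICATION.copy()


def exposure_summary_table() -> pd.DataFrame:
    """Printed per-assay exposure summary (copy)."""
    return EXPOSURE_SUMMARY.copy()


def published_auc(matrix: str, dose_mg_kg: float, assay: str) -> float:
    """Look up one printed AUC value, h·μg/mL."""
    t = EXPOSURE_SUMMARY
    row = t[(t.matrix == matrix) & (t.dose_mg_kg == dose_mg_kg) & (t.assay == assay)]
    if row.empty:
        raise KeyError((matrix, dose_mg_kg, assay))
    return float(row.iloc[0].auc)
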