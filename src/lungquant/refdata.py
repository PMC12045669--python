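"""Reference per-specimen measurements from the ex vivo rabbit cohort.

The six-thorax cohort study this pipeline models published its
per-specimen results in full; those printed columns are reproduced here as
inputs for cohort-summary computations and for checking the package's
statistics (the cohort means/SDs/CoVs are always recomputed from these
columns, never hard-coded downstream).

Units: delta P in cmH2O, compliance in mL/cmH2O, volumes in mL, T1 in ms,
concentrations in mM, Gd amounts in umol, PDF/PVF in percent.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SPECIMENS",
    "respiratory_table",
    "quantification_table",
    "distribution_table",
    "REGION_VOLUME_SUMMARY",
    "INSTILLATE",
]

SPECIMENS = [f"Specimen #{i}" for i in range(1, 7)]

_RESPIRATORY = {
    "delta_p_cmh2o": [-97.0, -94.0, -79.0, -110.0, -62.0, -89.0],
    "compliance_ml_per_cmh2o": [0.138, 0.134, 0.134, 0.098, 0.165, 0.131],
}

_QUANTIFICATION = {
    "enhanced_volume_ml": [31.8, 39.1, 45.8, 30.9, 37.7, 48.9],
    "t1_post_ms": [170.0, 285.3, 318.9, 166.5, 259.7, 397.0],
    "concentration_mm": [4.6, 1.8, 1.4, 4.6, 2.5, 0.9],
    "gd_amount_umol": [146.3, 70.4, 64.1, 142.1, 94.3, 44.0],
}

_DISTRIBUTION = {
    "pdf_pct": [83.0, 87.4, 79.1, 92.1, 78.1, 84.6],
    "pvf_pct": [35.7, 38.8, 23.6, 29.4, 33.7, 33.7],
}

#: Cohort mean +/- SD of the segmented region volumes (mL); the study
#: printed only the summary pair for these, not per-specimen values.
REGION_VOLUME_SUMMARY = {
    "TLV": (91.0, 5.4),
    "PER": (34.3, 6.8),
    "CER": (4.75, 0.9),
}

#: Instillate mixing protocol: surfactant volume, contrast-agent volume,
#: stock Gd3+ concentration, and volume effectively delivered.
INSTILLATE = {
    "surfactant_vol_ml": 2.7,
    "contrast_vol_ml": 0.27,
    "contrast_conc_mm": 500.0,
    "delivered_vol_ml": 2.2,
}


def respiratory_table() -> pd.DataFrame:
    """Per-specimen ventilation mechanics (delta P, compliance)."""
    return pd.DataFrame(_RESPIRATORY, index=SPECIMENS)


def quantification_table() -> pd.DataFrame:
    """Per-specimen enhanced volume, mean T1 post, concentration, amount."""
    return pd.DataFrame(_QUANTIFICATION, index=SPECIMENS)


def distribution_table() -> pd.DataFrame:
    """Per-specimen PDF and PVF percentages."""
    return pd.DataFrame(_DISTRIBUTION, index=SPECIMENS)
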