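"""Distribution metrics, slice profiles, MIPs, and cohort summaries.

Two scalar metrics summarize how an instilled surfactant + contrast bolus
distributed through the lung:

* PDF (peripheral distribution fraction): the Gd3+ amount found in the
  peripheral enhanced region (PER) over the total amount in PER + CER,
  in percent.  It measures partitioning between conducting airways and
  the distal lung.
* PVF (peripheral volume fraction): the PER volume over the total lung
  volume (TLV), in percent.  It measures how much of the lung the liquid
  reached.

Cohort statistics follow the small-cohort convention: arithmetic mean,
sample standard deviation (n - 1 denominator), and the coefficient of
variation CoV = SD / mean x 100%.  Cohort-level PVF/PDF are means of
per-specimen ratios, not ratios of pooled sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RegionLabels, Volume3D, region_volumes, resolve_axis
from .quantify import ConcentrationResult, gd_amount

__all__ = [
    "pdf_metric",
    "pvf_metric",
    "ProfileCurve",
    "slice_profile",
    "mip_render",
    "CohortSummary",
    "summarize_cohort",
    "SpecimenReport",
    "specimen_report",
    "cohort_table",
]


def pdf_metric(
    conc: ConcentrationResult,
    labels: RegionLabels,
    spacing,
    use_clamped: bool = True,
) -> float:
    """Peripheral distribution fraction, percent.

    100 x Q(PER) / (Q(PER) + Q(CER)), with Q the integrated Gd3+ amount.
    Clamped (non-negative) concentrations are used by default so the
    fraction stays in [0, 100] under noise.
    """
    if not labels.enhanced_mask.any():
        raise ValueError("PER and CER are both empty; PDF is undefined")
    q_per = gd_amount(conc, labels, spacing, "PER", use_clamped=use_clamped)
    q_cer = gd_amount(conc, labels, spacing, "CER", use_clamped=use_clamped)
    total = q_per + q_cer
    if total <= 0:
        raise ValueError("total enhanced Gd amount is zero; PDF is undefined")
    return 100.0 * q_per / total


def pvf_metric(labels: RegionLabels) -> float:
    """Peripheral volume fraction, percent: 100 x vol(PER) / vol(TLV).

    A pure volume ratio — identical voxel volumes cancel, so voxel counts
    suffice and concentrations never enter.
    """
    n_tlv = int(labels.tlv_mask.sum())
    if n_tlv == 0:
        raise ValueError("TLV is empty; PVF is undefined")
    return 100.0 * int(labels.per_mask.sum()) / n_tlv


@dataclass(frozen=True)
class ProfileCurve:
    """Slice-by-slice anatomical profile.

    ``table`` has one row per slice along the chosen anatomical axis:
    columns ``slice`` (index), ``position_mm`` (slice-center coordinate) and
    one column per region.  In quantity mode values are Gd3+ amounts per
    slice (umol) for PER and CER; in area mode they are in-plane region
    areas (mm^2) for TLV, PER and CER.
    """

    axis: str
    mode: str
    table: pd.DataFrame

    def region_total(self, region: str) -> float:
        return float(self.table[region].sum())


def slice_profile(
    field: Volume3D | None,
    labels: RegionLabels,
    spacing,
    axis: str,
    mode: str = "quantity",
    axes: tuple[str, str, str] | None = None,
) -> ProfileCurve:
    """Profile of Gd quantity or region area along an anatomical direction.

    ``axis`` is an anatomical name (e.g. ``"ventral-dorsal"`` for the
    supine dependent-region direction).  In quantity mode ``field`` is the
    concentration map (mM; clamped map recommended) and per-slice values sum
    exactly to the region's total amount.  In area mode ``field`` is unused.
    """
    if mode not in ("quantity", "area"):
        raise ValueError(f"mode must be 'quantity' or 'area', got {mode!r}")
    code = resolve_axis(axis)
    if field is not None:
        vol_axes = field.axes
    else:
        vol_axes = axes if axes is not None else ("RL", "VD", "CC")
    ax = tuple(resolve_axis(a) for a in vol_axes).index(code)

    n = labels.shape[ax]
    d = float(spacing[ax])
    positions = (np.arange(n) + 0.5) * d
    other = tuple(i for i in range(3) if i != ax)
    vox_ml = float(np.prod(spacing)) / 1000.0
    in_plane_mm2 = float(np.prod([spacing[i] for i in other]))

    data: dict[str, np.ndarray] = {}
    if mode == "quantity":
        if field is None:
            raise ValueError("quantity mode needs a concentration field")
        if field.shape != labels.shape:
            raise ValueError("field and labels shapes differ")
        c = np.nan_to_num(field.data, nan=0.0)
        for region in ("PER", "CER"):
            masked = np.where(labels.region_mask(region), c, 0.0)
            data[region] = masked.sum(axis=other) * vox_ml
    else:
        for region in ("TLV", "PER", "CER"):
            counts = labels.region_mask(region).sum(axis=other)
            data[region] = counts * in_plane_mm2

    table = pd.DataFrame({"slice": np.arange(n), "position_mm": positions, **data})
    return ProfileCurve(axis=code, mode=mode, table=table)


def mip_render(vol: Volume3D, axis: str) -> tuple[np.ndarray, tuple[float, float]]:
    """Maximum intensity projection along an anatomical direction.

    Returns the 2D image (per-ray maximum, NaN-ignoring) and the in-plane
    spacing of the remaining two axes, in mm.
    """
    import warnings

    ax = vol.axis_index(axis)
    with warnings.catch_warnings():
        # rays that are entirely NaN (outside the analysis mask) stay NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        img = np.nanmax(vol.data, axis=ax)
    other = tuple(i for i in range(3) if i != ax)
    return img, (vol.spacing[other[0]], vol.spacing[other[1]])


@dataclass(frozen=True)
class CohortSummary:
    """Mean, sample SD (n-1) and CoV (%) of one metric across specimens."""

    mean: float
    sd: float
    cov_pct: float
    n: int


def summarize_cohort(values) -> CohortSummary:
    """Cohort summary of a per-specimen metric list (n >= 2 finite values)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cohort summaries need at least two specimens")
    if not np.all(np.isfinite(v)):
        raise ValueError("cohort values must be finite")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    cov = abs(sd / mean) * 100.0 if mean != 0 else np.inf
    return CohortSummary(mean=mean, sd=sd, cov_pct=float(cov), n=int(v.size))


@dataclass(frozen=True)
class SpecimenReport:
    """Per-specimen distribution summary (one imaging session)."""

    enhanced_volume_ml: float
    mean_t1_post_ms: float
    mean_concentration_mm: float
    gd_amount_umol: float
    pdf_pct: float
    pvf_pct: float
    region_volumes_ml: dict[str, float] = field(default_factory=dict)
    invalid_voxel_count: int = 0
    negative_clamped_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pdf_pct <= 100.0:
            raise ValueError(f"PDF {self.pdf_pct} outside [0, 100]%")
        if not 0.0 <= self.pvf_pct <= 100.0:
            raise ValueError(f"PVF {self.pvf_pct} outside [0, 100]%")
        if self.gd_amount_umol < 0:
            raise ValueError("Gd amount cannot be negative")

    def as_dict(self) -> dict:
        d = {
            "enhanced_volume_ml": self.enhanced_volume_ml,
            "mean_t1_post_ms": self.mean_t1_post_ms,
            "mean_concentration_mm": self.mean_concentration_mm,
            "gd_amount_umol": self.gd_amount_umol,
            "pdf_pct": self.pdf_pct,
            "pvf_pct": self.pvf_pct,
            "invalid_voxel_count": self.invalid_voxel_count,
            "negative_clamped_count": self.negative_clamped_count,
        }
        for k, v in self.region_volumes_ml.items():
            d[f"volume_{k.lower()}_ml"] = v
        return d


def specimen_report(
    conc: ConcentrationResult, labels: RegionLabels, spacing
) -> SpecimenReport:
    """Summarize one specimen: volumes, mean T1_post / concentration over the
    enhanced region, integrated Gd amount, PDF and PVF."""
    vols = region_volumes(labels, spacing)
    enhanced = labels.enhanced_mask
    r1 = conc.r1_post.data[enhanced]
    r1 = r1[np.isfinite(r1) & (r1 > 0)]
    mean_t1 = float(np.mean(1000.0 / r1)) if r1.size else float("nan")
    c = conc.c_map_clamped.data[enhanced]
    c = c[np.isfinite(c)]
    mean_c = float(np.mean(c)) if c.size else float("nan")
    return SpecimenReport(
        enhanced_volume_ml=vols["PER"] + vols["CER"],
        mean_t1_post_ms=mean_t1,
        mean_concentration_mm=mean_c,
        gd_amount_umol=gd_amount(conc, labels, spacing, "enhanced"),
        pdf_pct=pdf_metric(conc, labels, spacing),
        pvf_pct=pvf_metric(labels),
        region_volumes_ml=vols,
        invalid_voxel_count=conc.invalid_voxel_count,
        negative_clamped_count=conc.negative_clamped_count,
    )


def cohort_table(reports, names=None) -> pd.DataFrame:
    """Per-specimen rows plus Mean / SD / CoV% rows for every numeric metric."""
    rows = [r.as_dict() for r in reports]
    idx = list(names) if names is not None else [f"specimen_{i+1}" for i in range(len(rows))]
    df = pd.DataFrame(rows, index=idx)
    numeric = df.select_dtypes("number")
    if len(df) >= 2:
        summary = pd.DataFrame(
            {
                col: {
                    "mean": numeric[col].mean(),
                    "sd": numeric[col].std(ddof=1),
                    "cov_pct": abs(numeric[col].std(ddof=1) / numeric[col].mean()) * 100.0
                    if numeric[col].mean() != 0
                    else np.inf,
                }
                for col in numeric.columns
            }
        ).T
        df = pd.concat([df, summary.T])
    return df
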