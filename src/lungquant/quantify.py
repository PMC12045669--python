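"""Calibration, R1 mapping and Gd3+ concentration quantification.

The chain mirrors the acquisition protocol:

1. Before contrast, the lung is imaged at several flip angles.  Mean ROI
   signals from a distal, solution-free region are jointly fitted to the
   spoiled-gradient model to give the scale constant A and the tissue
   relaxation rate R1_pre (a single scalar, by design: the protocol is
   ROI-based, not a pre-contrast map).
2. After contrast, a single volume at the largest flip angle is inverted
   voxel-by-voxel with that A, giving an R1_post map in s^-1.
3. Concentration follows from the linear relaxivity relation

       C [mM] = (R1_post - R1_pre) / r1,

   with r1 the agent's longitudinal relaxivity per Gd3+ ion (default
   3 mM^-1 s^-1).  Noise makes some raw concentrations negative; the policy
   is to clamp those to zero for amount integration while keeping the raw
   map, and to always report how many voxels were clamped.

Units: T1 in ms, R1 in s^-1 (R1 = 1000 / T1_ms), concentrations in mM,
voxel volumes in mL, so amount = C x volume is directly in umol
(mM * mL = umol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import AcquisitionParams, RegionLabels, Volume3D
from .signal_model import DEFAULT_T1_MAX_MS, invert_signal_map, ute_signal

__all__ = [
    "PreCalibration",
    "fit_pre_calibration",
    "calibrate_from_volumes",
    "R1MapResult",
    "r1_post_map",
    "ConcentrationResult",
    "concentration_map",
    "gd_amount",
    "instilled_gd_amount",
]


@dataclass(frozen=True)
class PreCalibration:
    """Joint (A, R1_pre) calibration from the pre-contrast flip-angle series."""

    r1_pre: float  # s^-1
    A: float  # scanner scale, arbitrary units
    fit_residual: float  # relative RMS of the flip-angle fit
    roi_voxel_count: int = 0

    def __post_init__(self) -> None:
        if self.r1_pre <= 0 or self.A <= 0:
            raise ValueError("calibration requires R1_pre > 0 and A > 0")
        if self.fit_residual < 0:
            raise ValueError("fit residual cannot be negative")

    @property
    def t1_pre_ms(self) -> float:
        return 1000.0 / self.r1_pre


def fit_pre_calibration(
    signals, params: AcquisitionParams, roi_voxel_count: int = 0
) -> PreCalibration:
    """Fit (A, R1_pre) to mean ROI signals across the flip-angle series.

    Initialization is the classic linearization S/sin(a) = E1 * S/tan(a) +
    A(1 - E1); the estimate is then refined by nonlinear least squares on
    the signal equation itself.  At least two distinct flip angles and
    strictly positive signals are required.
    """
    s = np.asarray(signals, dtype=float)
    alphas = np.asarray(params.flip_angles_deg, dtype=float)
    if s.shape != alphas.shape:
        raise ValueError(
            f"got {s.size} signals for {alphas.size} flip angles; one mean signal per angle"
        )
    if s.size < 2 or np.unique(alphas).size < 2:
        raise ValueError("need signals at >= 2 distinct flip angles")
    if np.any(s <= 0):
        raise ValueError("all ROI signals must be > 0")

    rad = np.deg2rad(alphas)
    # Linearized solve: slope = E1, intercept = A (1 - E1).
    x = s / np.tan(rad)
    y = s / np.sin(rad)
    slope, intercept = np.polyfit(x, y, 1)
    if not 0.0 < slope < 1.0:
        raise ValueError(
            f"linearized fit gives saturation factor E1 = {slope:.4g} outside (0, 1); "
            "the signal series is inconsistent with the spoiled-gradient model"
        )
    t1_0 = -params.tr_ms / np.log(slope)
    a_0 = intercept / (1.0 - slope)

    def resid(theta):
        a, t1 = theta
        return ute_signal(a, alphas, params.tr_ms, t1) - s

    sol = least_squares(
        resid,
        x0=[max(a_0, 1e-6), float(np.clip(t1_0, 1e-3, 1e6))],
        bounds=([1e-12, 1e-6], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a_hat, t1_hat = sol.x
    e1 = np.exp(-params.tr_ms / t1_hat)
    if not 0.0 < e1 < 1.0:
        raise ValueError(f"refined fit left the model domain (E1 = {e1:.4g})")
    residual = float(np.sqrt(np.mean(sol.fun**2)) / np.sqrt(np.mean(s**2)))
    return PreCalibration(
        r1_pre=1000.0 / t1_hat,
        A=float(a_hat),
        fit_residual=residual,
        roi_voxel_count=int(roi_voxel_count),
    )


def calibrate_from_volumes(
    pre_volumes, params: AcquisitionParams, roi_mask: np.ndarray
) -> PreCalibration:
    """Mean-ROI signals from one pre-contrast volume per flip angle, then fit."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("calibration ROI is empty")
    if len(pre_volumes) != len(params.flip_angles_deg):
        raise ValueError(
            f"{len(pre_volumes)} pre-contrast volumes for "
            f"{len(params.flip_angles_deg)} flip angles"
        )
    signals = [float(np.mean(v.data[roi_mask])) for v in pre_volumes]
    return fit_pre_calibration(signals, params, roi_voxel_count=int(roi_mask.sum()))


@dataclass(frozen=True)
class R1MapResult:
    """Voxel-wise post-contrast relaxation-rate map (s^-1, NaN = invalid)."""

    r1_map: Volume3D
    invalid_voxel_count: int
    capped_voxel_count: int


def r1_post_map(
    post_vol: Volume3D,
    calib: PreCalibration,
    params: AcquisitionParams,
    mask: np.ndarray,
    t1_max_ms: float = DEFAULT_T1_MAX_MS,
) -> R1MapResult:
    """Invert the post-contrast volume (acquired at the post flip angle).

    Voxels outside the mask and voxels violating the model domain
    (S >= A sin(alpha) or S <= 0) are NaN; they are excluded from every
    downstream sum and reported in the diagnostics.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != post_vol.shape:
        raise ValueError("analysis mask shape does not match the volume")
    if not mask.any():
        raise ValueError("analysis mask is empty")
    inv = invert_signal_map(
        post_vol.data, calib.A, params.post_flip_angle_deg, params.tr_ms, t1_max_ms
    )
    r1 = 1000.0 / inv.t1_ms
    r1 = np.where(mask, r1, np.nan)
    invalid_in_mask = int((mask & np.isnan(inv.t1_ms)).sum())
    capped_in_mask = int((mask & ~np.isnan(inv.t1_ms) & (inv.t1_ms >= t1_max_ms)).sum())
    return R1MapResult(
        post_vol.with_data(r1, allow_nan=True), invalid_in_mask, capped_in_mask
    )


@dataclass(frozen=True)
class ConcentrationResult:
    """Per-voxel Gd3+ concentration with clamping diagnostics.

    ``c_map`` is the raw signed map (NaN = invalid voxel); ``c_map_clamped``
    has negatives set to zero, the form used for amount integration and the
    distribution metrics.
    """

    c_map: Volume3D  # mM, raw
    r1_post: Volume3D  # s^-1
    r1_pre: float  # s^-1
    invalid_voxel_count: int
    negative_clamped_count: int

    @property
    def c_map_clamped(self) -> Volume3D:
        return self.c_map.with_data(
            np.where(np.isnan(self.c_map.data), np.nan, np.maximum(self.c_map.data, 0.0)),
            allow_nan=True,
        )


def concentration_map(
    r1_post: R1MapResult,
    calib: PreCalibration,
    params: AcquisitionParams,
    clamp_negative: bool = True,
) -> ConcentrationResult:
    """Apply the relaxivity relation C = (R1_post - R1_pre) / r1 per voxel."""
    c = (r1_post.r1_map.data - calib.r1_pre) / params.r1
    finite = ~np.isnan(c)
    negative = int((finite & (c < 0)).sum()) if clamp_negative else 0
    return ConcentrationResult(
        c_map=r1_post.r1_map.with_data(c, allow_nan=True),
        r1_post=r1_post.r1_map,
        r1_pre=calib.r1_pre,
        invalid_voxel_count=r1_post.invalid_voxel_count,
        negative_clamped_count=negative,
    )


def gd_amount(
    conc: ConcentrationResult,
    labels: RegionLabels,
    spacing,
    region: str = "enhanced",
    use_clamped: bool = True,
) -> float:
    """Integrated Gd3+ amount over a region, in umol.

    Sums C (mM) x voxel volume (mL) over the region's voxels; invalid (NaN)
    voxels contribute zero.  ``region`` is one of TLV, PER, CER, enhanced.
    """
    mask = labels.region_mask(region)
    if mask.shape != conc.c_map.shape:
        raise ValueError("labels do not match the concentration grid")
    c = (conc.c_map_clamped if use_clamped else conc.c_map).data
    vox_ml = float(np.prod(spacing)) / 1000.0
    return float(np.nansum(c[mask]) * vox_ml)


def instilled_gd_amount(
    surfactant_vol_ml: float,
    contrast_vol_ml: float,
    contrast_conc_mm: float,
    delivered_vol_ml: float,
) -> float:
    """Nominal instilled Gd3+ amount (umol) from the mixing protocol.

    The contrast agent is diluted into the surfactant, so the delivered
    amount is delivered volume x mixture concentration:
    delivered * contrast_vol / (surfactant_vol + contrast_vol) * stock_conc.
    """
    if surfactant_vol_ml <= 0 or contrast_vol_ml <= 0 or contrast_conc_mm <= 0:
        raise ValueError("component volumes and stock concentration must be > 0")
    if delivered_vol_ml < 0:
        raise ValueError("delivered volume cannot be negative")
    total = surfactant_vol_ml + contrast_vol_ml
    if delivered_vol_ml > total:
        raise ValueError(
            f"delivered volume {delivered_vol_ml} mL exceeds prepared mixture {total} mL"
        )
    return delivered_vol_ml * contrast_vol_ml / total * contrast_conc_mm
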