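"""Steady-state spoiled-gradient (UTE) signal model and its inversion.

The forward model for the magnitude signal at flip angle alpha, repetition
time TR and longitudinal relaxation time T1 is

    S = A * sin(alpha) * (1 - E1) / (1 - cos(alpha) * E1),   E1 = exp(-TR/T1)

with A a scanner- and proton-density-dependent scale constant.  TE is short
enough (~0.1 ms) that T2* decay is neglected; there is no TE term.

Interfaces take flip angles in degrees (the convention of acquisition
protocols); radians are used internally only.

The closed-form inversion solves the same equation for E1,

    E1 = (A sin(alpha) - S) / (A sin(alpha) - S cos(alpha)),  T1 = -TR / ln E1,

valid for 0 < S < A sin(alpha).  On noisy magnitude maps some voxels always
violate that domain; the map-level inverter flags them with NaN and counts
them instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Volume3D

__all__ = [
    "ute_signal",
    "invert_signal_to_T1",
    "invert_signal_map",
    "T1MapInversion",
    "signal_enhancement",
    "roi_snr",
    "DEFAULT_T1_MAX_MS",
]

#: Cap for the inversion as S -> 0+ (background air): T1 diverges, so it is
#: clipped here and the voxel flagged as capped.
DEFAULT_T1_MAX_MS = 5000.0


def _check_geometry(alpha_deg, tr_ms) -> tuple[np.ndarray, float]:
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(alpha <= 0.0) or np.any(alpha > 90.0):
        raise ValueError(f"flip angle must lie in (0, 90] degrees, got {alpha_deg}")
    tr = float(tr_ms)
    if tr <= 0:
        raise ValueError("TR must be > 0")
    return alpha, tr


def ute_signal(A, alpha_deg, tr_ms, t1_ms):
    """Forward signal amplitude; vectorized over any argument.

    Strictly decreasing in T1 (more saturation) and linear in A.
    """
    alpha, tr = _check_geometry(alpha_deg, tr_ms)
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be > 0")
    rad = np.deg2rad(alpha)
    e1 = np.exp(-tr / t1)
    out = np.asarray(A, dtype=float) * np.sin(rad) * (1.0 - e1) / (1.0 - np.cos(rad) * e1)
    return float(out) if np.isscalar(t1_ms) and np.isscalar(A) and np.isscalar(alpha_deg) else out


def invert_signal_to_T1(S, A, alpha_deg, tr_ms, t1_max_ms: float = DEFAULT_T1_MAX_MS) -> float:
    """Closed-form T1 (ms) from a single-flip-angle signal; scalar, strict.

    Raises when S is outside (0, A sin(alpha)); near-zero signals whose T1
    exceeds ``t1_max_ms`` are returned capped at that value.
    """
    alpha, tr = _check_geometry(alpha_deg, tr_ms)
    rad = float(np.deg2rad(alpha))
    ceil = A * np.sin(rad)
    if S >= ceil:
        raise ValueError(
            f"signal {S} exceeds model ceiling A*sin(alpha) = {ceil:.6g}"
        )
    if S <= 0:
        raise ValueError("signal must be > 0")
    e1 = (ceil - S) / (ceil - S * np.cos(rad))
    t1 = -tr / np.log(e1)
    return min(float(t1), float(t1_max_ms))


@dataclass(frozen=True)
class T1MapInversion:
    """Result of per-voxel inversion: T1 map (ms) with NaN sentinels."""

    t1_ms: np.ndarray
    invalid_count: int
    capped_count: int


def invert_signal_map(
    signal: np.ndarray,
    A: float,
    alpha_deg: float,
    tr_ms: float,
    t1_max_ms: float = DEFAULT_T1_MAX_MS,
) -> T1MapInversion:
    """Vectorized inversion with the out-of-domain policy for noisy maps.

    Voxels with S <= 0 or S >= A sin(alpha) become NaN and are counted as
    invalid; voxels whose T1 would exceed ``t1_max_ms`` are capped there and
    counted separately.
    """
    alpha, tr = _check_geometry(alpha_deg, tr_ms)
    rad = float(np.deg2rad(alpha))
    s = np.asarray(signal, dtype=float)
    ceil = A * np.sin(rad)
    valid = (s > 0.0) & (s < ceil)
    e1 = np.where(valid, (ceil - s) / (ceil - s * np.cos(rad)), 0.5)
    t1 = -tr / np.log(e1)
    capped = valid & (t1 > t1_max_ms)
    t1 = np.where(capped, t1_max_ms, t1)
    t1 = np.where(valid, t1, np.nan)
    return T1MapInversion(t1, int((~valid).sum()), int(capped.sum()))


def signal_enhancement(snr_pre: float, snr_post: float) -> float:
    """Signal enhancement SE = (SNR_post - SNR_pre) / SNR_pre, as a fraction.

    Multiply by 100 for the percent convention used in reports.  Negative
    values (signal loss) are permitted.
    """
    if snr_pre <= 0:
        raise ValueError("SNR before contrast must be > 0")
    return (snr_post - snr_pre) / snr_pre


def roi_snr(vol: Volume3D, signal_mask: np.ndarray, noise_mask: np.ndarray) -> float:
    """Mean signal in an ROI over the standard deviation in a noise ROI.

    A declared convention: the estimator needs disjoint, non-empty masks and
    a noise region with non-zero variance.
    """
    signal_mask = np.asarray(signal_mask, dtype=bool)
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if not signal_mask.any() or not noise_mask.any():
        raise ValueError("signal and noise masks must both be non-empty")
    if (signal_mask & noise_mask).any():
        raise ValueError("signal and noise masks overlap")
    noise_sd = float(np.std(vol.data[noise_mask]))
    if noise_sd == 0.0:
        raise ValueError("noise ROI has zero variance; cannot form SNR")
    return float(np.mean(vol.data[signal_mask])) / noise_sd
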