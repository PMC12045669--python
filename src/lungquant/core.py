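"""Core volumetric containers, acquisition parameters, and region labels.

Everything downstream (signal modelling, quantification, segmentation,
metrics) moves data around in these types.  The anatomical axis convention
is fixed once here: the canonical array order is

    axis 0: right -> left        (code ``RL``)
    axis 1: ventral -> dorsal    (code ``VD``)
    axis 2: cranial -> caudal    (code ``CC``)

i.e. a supine subject with gravity pointing along increasing axis 1.  All
profile and projection operations take anatomical direction names, never raw
array axes, so volumes stored in a permuted order remain safe as long as
their ``axes`` tuple says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "AXIS_CODES",
    "CANONICAL_AXES",
    "Volume3D",
    "AcquisitionParams",
    "RegionLabels",
    "region_volumes",
    "resolve_axis",
    "LABEL_BACKGROUND",
    "LABEL_TLV_ONLY",
    "LABEL_PER",
    "LABEL_CER",
    "REGION_NAMES",
]

AXIS_CODES = ("RL", "VD", "CC")
CANONICAL_AXES = ("RL", "VD", "CC")

#: Accepted spellings for each anatomical direction.
_AXIS_ALIASES: Mapping[str, str] = {
    "RL": "RL",
    "right-left": "RL",
    "right->left": "RL",
    "VD": "VD",
    "ventral-dorsal": "VD",
    "ventral->dorsal": "VD",
    "CC": "CC",
    "cranial-caudal": "CC",
    "cranial->caudal": "CC",
}

LABEL_BACKGROUND = 0
LABEL_TLV_ONLY = 1
LABEL_PER = 2
LABEL_CER = 3

REGION_NAMES = ("TLV", "PER", "CER", "enhanced")


def resolve_axis(name: str) -> str:
    """Normalize an anatomical direction name to its two-letter code."""
    try:
        return _AXIS_ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown anatomical axis {name!r}; expected one of "
            f"{sorted(set(_AXIS_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar voxel grid with physical spacing and anatomical axes.

    Parameters
    ----------
    data:
        3D array.  Units depend on role: raw signal (arbitrary units),
        R1 (s^-1), T1 (ms), or concentration (mM).
    spacing:
        Voxel pitch ``(d0, d1, d2)`` in mm along the three array axes.
    axes:
        Anatomical direction of each array axis, a permutation of
        ``("RL", "VD", "CC")``.
    allow_nan:
        Maps produced by per-voxel inversion carry NaN as the
        invalid-voxel sentinel; such maps must opt in explicitly.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = CANONICAL_AXES
    allow_nan: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {data.ndim} dimensions")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be three strictly positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        axes = tuple(resolve_axis(a) for a in self.axes)
        if sorted(axes) != sorted(AXIS_CODES):
            raise ValueError(f"axes must be a permutation of {AXIS_CODES}, got {self.axes}")
        object.__setattr__(self, "axes", axes)
        if not self.allow_nan and np.isnan(data).any():
            raise ValueError(
                "volume contains NaN; mask explicitly or construct with allow_nan=True"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3)."""
        d0, d1, d2 = self.spacing
        return d0 * d1 * d2 / 1000.0

    def axis_index(self, direction: str) -> int:
        """Array axis carrying the given anatomical direction."""
        return self.axes.index(resolve_axis(direction))

    def with_data(self, data: np.ndarray, allow_nan: bool | None = None) -> "Volume3D":
        """Same grid, new voxel values."""
        return Volume3D(
            data,
            self.spacing,
            self.axes,
            allow_nan=self.allow_nan if allow_nan is None else allow_nan,
        )

    def canonical(self) -> "Volume3D":
        """Transpose to the canonical (RL, VD, CC) axis order."""
        order = tuple(self.axes.index(code) for code in CANONICAL_AXES)
        return Volume3D(
            np.transpose(self.data, order),
            tuple(self.spacing[i] for i in order),
            CANONICAL_AXES,
            allow_nan=self.allow_nan,
        )

    def same_grid(self, other: "Volume3D", tol_mm: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and self.axes == other.axes
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
        )


@dataclass(frozen=True)
class AcquisitionParams:
    """UTE spoiled-gradient acquisition parameters.

    ``te_ms`` is recorded for provenance only: the steady-state signal
    equation used throughout carries no TE term (T2* decay over ~0.1 ms is
    neglected).  ``r1`` is the longitudinal relaxivity of the contrast agent
    per Gd3+ ion in mM^-1 s^-1.
    """

    tr_ms: float = 3.7
    te_ms: float = 0.096
    flip_angles_deg: tuple[float, ...] = (5.0, 8.0, 16.0, 25.0)
    r1: float = 3.0
    post_flip_angle_deg: float = 25.0
    voxel_mm: tuple[float, float, float] = (0.78, 0.78, 1.0)

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("TR must be > 0")
        object.__setattr__(self, "flip_angles_deg", tuple(float(a) for a in self.flip_angles_deg))
        for a in self.flip_angles_deg:
            if not 0.0 < a <= 90.0:
                raise ValueError(f"flip angle {a} out of (0, 90] degrees")
        if self.r1 <= 0:
            raise ValueError("relaxivity r1 must be > 0")
        if not any(np.isclose(self.post_flip_angle_deg, a) for a in self.flip_angles_deg):
            raise ValueError(
                f"post flip angle {self.post_flip_angle_deg} not among {self.flip_angles_deg}"
            )


@dataclass(frozen=True)
class RegionLabels:
    """Voxel-wise partition of the thorax into analysis regions.

    Encoding (one integer label per voxel, regions mutually exclusive):

    ====== =========================================================
    value  meaning
    ====== =========================================================
    0      background (outside the lung)
    1      TLV-only: lung voxels without contrast enhancement
    2      PER: peripheral enhanced region
    3      CER: central enhanced region (enhanced central airways)
    ====== =========================================================

    TLV (total lung volume, airways included) is the union of {1, 2, 3},
    so PER and CER are disjoint by construction and both subsets of TLV.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got {labels.ndim} dimensions")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("labels must be integer-valued")
            labels = labels.astype(np.int16)
        present = np.unique(labels)
        bad = sorted(int(v) for v in present if v not in (0, 1, 2, 3))
        if bad:
            raise ValueError(f"unknown label values {bad}; allowed values are 0..3")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def tlv_mask(self) -> np.ndarray:
        return self.labels > LABEL_BACKGROUND

    @property
    def per_mask(self) -> np.ndarray:
        return self.labels == LABEL_PER

    @property
    def cer_mask(self) -> np.ndarray:
        return self.labels == LABEL_CER

    @property
    def enhanced_mask(self) -> np.ndarray:
        return (self.labels == LABEL_PER) | (self.labels == LABEL_CER)

    def region_mask(self, region: str) -> np.ndarray:
        region = region.upper() if region.lower() != "enhanced" else "enhanced"
        if region == "TLV":
            return self.tlv_mask
        if region == "PER":
            return self.per_mask
        if region == "CER":
            return self.cer_mask
        if region == "enhanced":
            return self.enhanced_mask
        raise ValueError(f"unknown region {region!r}; expected one of {REGION_NAMES}")


def region_volumes(
    labels: RegionLabels, spacing: tuple[float, float, float]
) -> dict[str, float]:
    """Per-region volumes in mL: voxel count x dx*dy*dz / 1000.

    Returns TLV, PER and CER.  TLV >= max(PER, CER) always; TLV is not
    required to equal PER + CER because unenhanced lung (TLV-only) exists.
    """
    vox_ml = float(np.prod(spacing)) / 1000.0
    return {
        "TLV": int(labels.tlv_mask.sum()) * vox_ml,
        "PER": int(labels.per_mask.sum()) * vox_ml,
        "CER": int(labels.cer_mask.sum()) * vox_ml,
    }
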