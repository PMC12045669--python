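"""Region ingestion and a transparent fallback segmenter.

The pipeline's region partition (TLV / PER / CER) normally comes from an
external source — manual delineation or a trained network — ingested as a
label volume or as separate binary masks.  For phantom-driven testing and
for quick looks at new data, a rule-based fallback segmenter is provided.
It is deliberately simple plumbing, not a learned model:

* enhanced voxels are those whose voxel-wise signal enhancement
  (post - pre) / pre exceeds a threshold (default 1.0, i.e. a 100%
  signal increase), inside a supplied lung mask;
* the central enhanced region (CER) is the subset of enhanced voxels
  belonging to airway-calibre tubes connected to the trachea: the enhanced
  mask is closed (airway walls are thin hollow shells, which a plain
  opening would erase), opened with a ball of the central tube radius,
  and the component connected to the trachea seed is kept;
* PER is the remaining enhancement; TLV is the lung mask united with the
  enhancement.

The segmenter is deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    LABEL_CER,
    LABEL_PER,
    LABEL_TLV_ONLY,
    RegionLabels,
    Volume3D,
)
from .io import read_labels

__all__ = [
    "SegmentationConfig",
    "ingest_labels",
    "labels_from_masks",
    "fallback_segment",
    "dice_coefficient",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the fallback segmenter.

    enhancement_threshold:
        voxel-wise SE fraction above which a voxel counts as enhanced
        (1.0 = signal doubled).
    min_component_voxels:
        connected components smaller than this are dropped as noise.
    central_radius_mm:
        tube radius separating central airways from peripheral blobs.
    closing_radius_mm:
        radius of the closing that fills hollow airway lumens before the
        central opening.
    trachea_seed:
        voxel index of a point inside the trachea, or "auto" (centroid of
        the most cranial enhanced slice).
    pre_signal_floor:
        denominator floor for the SE ratio; None derives it as 20% of the
        median pre-contrast signal inside the lung mask, guarding against
        division by near-zero air signal.
    """

    enhancement_threshold: float = 1.0
    min_component_voxels: int = 20
    central_radius_mm: float = 1.6
    closing_radius_mm: float = 2.0
    trachea_seed: tuple[int, int, int] | str = "auto"
    pre_signal_floor: float | None = None

    def __post_init__(self) -> None:
        if self.enhancement_threshold <= 0:
            raise ValueError("enhancement threshold must be > 0")
        if self.central_radius_mm <= 0 or self.closing_radius_mm <= 0:
            raise ValueError("morphology radii must be > 0")


def ingest_labels(path, grid: Volume3D) -> RegionLabels:
    """Load an external label volume, validated against the analysis grid."""
    return read_labels(path, grid=grid)


def labels_from_masks(
    tlv_mask: np.ndarray,
    per_mask: np.ndarray,
    enhanced_mask: np.ndarray | None = None,
    cer_mask: np.ndarray | None = None,
) -> RegionLabels:
    """Assemble RegionLabels from binary masks.

    When only PER and a combined enhanced mask are available, CER is the
    complement of PER within the enhancement.  PER/CER are forced inside
    TLV by uniting TLV with the enhancement (enhanced lung is lung).
    """
    tlv = np.asarray(tlv_mask, dtype=bool)
    per = np.asarray(per_mask, dtype=bool)
    if cer_mask is not None:
        cer = np.asarray(cer_mask, dtype=bool) & ~per
    elif enhanced_mask is not None:
        cer = np.asarray(enhanced_mask, dtype=bool) & ~per
    else:
        cer = np.zeros_like(per)
    labels = np.zeros(tlv.shape, dtype=np.int16)
    labels[tlv | per | cer] = LABEL_TLV_ONLY
    labels[per] = LABEL_PER
    labels[cer] = LABEL_CER
    return RegionLabels(labels)


def _ball_mm(radius_mm: float, spacing) -> np.ndarray:
    """Anisotropy-aware ball structuring element of a physical radius."""
    half = [max(1, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    return sum(g**2 for g in grids) <= radius_mm**2


def _auto_trachea_seed(filled: np.ndarray, cranial_axis: int) -> tuple[int, ...]:
    """Centroid of the most cranial non-empty slice of the filled mask."""
    moved = np.moveaxis(filled, cranial_axis, 0)
    occupancy = moved.reshape(moved.shape[0], -1).any(axis=1)
    first = int(np.argmax(occupancy))
    coords = np.argwhere(moved[first])
    center = np.round(coords.mean(axis=0)).astype(int)
    seed = [0, 0, 0]
    seed[cranial_axis] = first
    rest = [i for i in range(3) if i != cranial_axis]
    for axis, value in zip(rest, center):
        seed[axis] = int(value)
    return tuple(seed)


def fallback_segment(
    pre: Volume3D,
    post: Volume3D,
    cfg: SegmentationConfig,
    lung_mask: np.ndarray,
) -> RegionLabels:
    """Threshold-and-morphology segmentation of pre/post volume pairs."""
    if not pre.same_grid(post):
        raise ValueError(
            f"pre {pre.shape} @ {pre.spacing} and post {post.shape} @ {post.spacing} "
            "are not on the same grid"
        )
    lung = np.asarray(lung_mask, dtype=bool)
    if lung.shape != pre.shape:
        raise ValueError("lung mask shape does not match the volumes")
    if not lung.any():
        raise ValueError("lung mask is empty")

    floor = cfg.pre_signal_floor
    if floor is None:
        floor = 0.2 * float(np.median(pre.data[lung]))
    floor = max(floor, np.finfo(float).tiny)
    se = (post.data - pre.data) / np.maximum(pre.data, floor)

    enhanced = (se > cfg.enhancement_threshold) & lung
    if cfg.min_component_voxels > 1:
        comp, n = ndimage.label(enhanced)
        if n:
            sizes = np.bincount(comp.ravel())
            keep = sizes >= cfg.min_component_voxels
            keep[0] = False
            enhanced = keep[comp]
    if not enhanced.any():
        raise ValueError(
            "no voxels exceed the enhancement threshold; review "
            "enhancement_threshold against the observed pre/post contrast"
        )

    # Fill hollow airway lumens, then keep only airway-calibre structures.
    spacing = pre.spacing
    filled = ndimage.binary_closing(enhanced, structure=_ball_mm(cfg.closing_radius_mm, spacing))
    filled |= enhanced
    core = ndimage.binary_opening(filled, structure=_ball_mm(cfg.central_radius_mm, spacing))

    cer = np.zeros_like(enhanced)
    if core.any():
        cranial_axis = pre.axis_index("cranial-caudal")
        seed = (
            _auto_trachea_seed(filled, cranial_axis)
            if isinstance(cfg.trachea_seed, str)
            else tuple(int(v) for v in cfg.trachea_seed)
        )
        comp, n = ndimage.label(core)
        label_at_seed = comp[seed]
        if label_at_seed == 0:
            # Seed sits just outside the opened core (it erodes tube ends);
            # take the component nearest to the seed.
            coords = np.argwhere(core)
            d2 = ((coords - np.asarray(seed)) * np.asarray(spacing)) ** 2
            label_at_seed = comp[tuple(coords[int(np.argmin(d2.sum(axis=1)))])]
        central = comp == label_at_seed
        central = ndimage.binary_dilation(central, structure=_ball_mm(min(spacing) * 1.5, spacing))
        cer = enhanced & central
    per = enhanced & ~cer

    labels = np.zeros(pre.shape, dtype=np.int16)
    labels[lung | enhanced] = LABEL_TLV_ONLY
    labels[per] = LABEL_PER
    labels[cer] = LABEL_CER
    return RegionLabels(labels)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
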