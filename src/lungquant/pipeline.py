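"""End-to-end orchestration: calibrate -> map -> segment/ingest -> report.

Two entry levels:

* :func:`analyze_specimen` — in-memory chain for library users (and the
  phantom-driven tests): pre-contrast series + post volume + region labels
  + calibration ROI in, :class:`SpecimenAnalysis` out.
* :func:`run_specimen` / :func:`run_cohort` — file-driven runs from a
  :class:`PipelineConfig`: read NIfTI inputs, write R1/concentration maps,
  slice profiles, MIPs, and JSON/CSV reports with a provenance header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .core import AcquisitionParams, RegionLabels, Volume3D
from .io import load_params, read_labels, read_volume, write_volume
from .metrics import (
    SpecimenReport,
    cohort_table,
    mip_render,
    slice_profile,
    specimen_report,
)
from .quantify import (
    ConcentrationResult,
    PreCalibration,
    calibrate_from_volumes,
    concentration_map,
    r1_post_map,
)
from .segment import SegmentationConfig, fallback_segment
from .signal_model import DEFAULT_T1_MAX_MS

__all__ = [
    "SpecimenAnalysis",
    "analyze_specimen",
    "PipelineConfig",
    "run_specimen",
    "run_cohort",
]


@dataclass(frozen=True)
class SpecimenAnalysis:
    calibration: PreCalibration
    concentration: ConcentrationResult
    labels: RegionLabels
    report: SpecimenReport


def analyze_specimen(
    pre_volumes,
    post_volume: Volume3D,
    labels: RegionLabels,
    params: AcquisitionParams,
    calibration_roi: np.ndarray,
    analysis_mask: np.ndarray | None = None,
    clamp_negative: bool = True,
    t1_max_ms: float = DEFAULT_T1_MAX_MS,
) -> SpecimenAnalysis:
    """Full quantification chain on in-memory volumes.

    The analysis mask defaults to the enhanced region (PER + CER), which is
    where concentrations and amounts are defined.
    """
    calib = calibrate_from_volumes(pre_volumes, params, calibration_roi)
    mask = labels.enhanced_mask if analysis_mask is None else np.asarray(analysis_mask, bool)
    r1 = r1_post_map(post_volume, calib, params, mask, t1_max_ms=t1_max_ms)
    conc = concentration_map(r1, calib, params, clamp_negative=clamp_negative)
    report = specimen_report(conc, labels, post_volume.spacing)
    return SpecimenAnalysis(calibration=calib, concentration=conc, labels=labels, report=report)


@dataclass(frozen=True)
class PipelineConfig:
    """File-level description of one specimen run.

    ``labels_path`` supplies externally produced regions; when absent, the
    fallback segmenter runs on the pre/post pair and needs ``lung_mask_path``.
    """

    pre_paths: tuple[str, ...]
    post_path: str
    calibration_roi_path: str
    output_dir: str
    labels_path: str | None = None
    lung_mask_path: str | None = None
    params_path: str | None = None
    params: AcquisitionParams | None = None
    segmentation: SegmentationConfig | None = None
    clamp_negative: bool = True
    name: str = "specimen"

    def resolve_params(self) -> AcquisitionParams:
        if self.params is not None:
            return self.params
        if self.params_path is not None:
            return load_params(self.params_path)
        return AcquisitionParams()

    def validate(self) -> None:
        missing = [
            ("pre_paths", p) for p in self.pre_paths if not Path(p).exists()
        ]
        for field_name in ("post_path", "calibration_roi_path", "labels_path", "lung_mask_path", "params_path"):
            value = getattr(self, field_name)
            if value is not None and not Path(value).exists():
                missing.append((field_name, value))
        if missing:
            details = ", ".join(f"{f}={p!r}" for f, p in missing)
            raise FileNotFoundError(f"missing pipeline inputs: {details}")
        params = self.resolve_params()
        if len(self.pre_paths) != len(params.flip_angles_deg):
            raise ValueError(
                f"{len(self.pre_paths)} pre-contrast volumes for "
                f"{len(params.flip_angles_deg)} flip angles"
            )
        if self.labels_path is None and self.lung_mask_path is None:
            raise ValueError(
                "either labels_path (external regions) or lung_mask_path "
                "(for the fallback segmenter) is required"
            )


def _provenance(cfg: PipelineConfig) -> dict:
    payload = json.dumps(
        dataclasses.asdict(cfg), sort_keys=True, default=str
    ).encode()
    return {
        "package_version": __version__,
        "config_sha1": hashlib.sha1(payload).hexdigest(),
    }


def run_specimen(cfg: PipelineConfig) -> SpecimenAnalysis:
    """Execute one specimen end to end, writing all artifacts.

    Outputs under ``cfg.output_dir``: r1_post.nii.gz, concentration.nii.gz,
    labels.nii.gz (when segmented here), profile CSVs, MIP PNGs,
    report.json and report.csv, calibration.json.
    """
    cfg.validate()
    params = cfg.resolve_params()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pre_volumes = [read_volume(p) for p in cfg.pre_paths]
    post = read_volume(cfg.post_path)
    roi = read_volume(cfg.calibration_roi_path).data > 0

    if cfg.labels_path is not None:
        labels = read_labels(cfg.labels_path, grid=post)
    else:
        lung = read_volume(cfg.lung_mask_path).data > 0
        labels = fallback_segment(
            pre_volumes[-1], post, cfg.segmentation or SegmentationConfig(), lung
        )
        from .io import write_labels

        write_labels(labels, post.spacing, out / "labels.nii.gz")

    analysis = analyze_specimen(
        pre_volumes, post, labels, params, roi, clamp_negative=cfg.clamp_negative
    )

    write_volume(analysis.concentration.r1_post, out / "r1_post.nii.gz")
    write_volume(analysis.concentration.c_map_clamped, out / "concentration.nii.gz")

    clamped = analysis.concentration.c_map_clamped
    for axis, tag in (("ventral-dorsal", "vd"), ("right-left", "rl")):
        prof = slice_profile(clamped, labels, post.spacing, axis, "quantity")
        prof.table.to_csv(out / f"profile_quantity_{tag}.csv", index=False)
    area = slice_profile(None, labels, post.spacing, "ventral-dorsal", "area", axes=post.axes)
    area.table.to_csv(out / "profile_area_vd.csv", index=False)

    _write_mips(clamped, out)

    calib = analysis.calibration
    (out / "calibration.json").write_text(
        json.dumps(
            {
                "A": calib.A,
                "r1_pre_s": calib.r1_pre,
                "t1_pre_ms": calib.t1_pre_ms,
                "fit_residual": calib.fit_residual,
                "roi_voxel_count": calib.roi_voxel_count,
                "invalid_voxel_count": analysis.concentration.invalid_voxel_count,
                "negative_clamped_count": analysis.concentration.negative_clamped_count,
                **_provenance(cfg),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    report = {**analysis.report.as_dict(), **_provenance(cfg)}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    import pandas as pd

    pd.DataFrame([analysis.report.as_dict()], index=[cfg.name]).to_csv(out / "report.csv")
    return analysis


def _write_mips(vol: Volume3D, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for axis, tag in (
        ("ventral-dorsal", "coronal"),
        ("right-left", "sagittal"),
        ("cranial-caudal", "axial"),
    ):
        img, _spacing = mip_render(vol, axis)
        np.save(out / f"mip_{tag}.npy", img)
        plt.imsave(out / f"mip_{tag}.png", np.nan_to_num(img).T, cmap="inferno", origin="lower")


def run_cohort(cfgs, output_dir) -> "pd.DataFrame":
    """Run several specimens and write a cohort mean/SD/CoV table."""
    import pandas as pd

    if len(cfgs) < 2:
        raise ValueError("cohort summaries need at least two specimens")
    reports = []
    names = []
    for cfg in cfgs:
        reports.append(run_specimen(cfg).report)
        names.append(cfg.name)
    table = cohort_table(reports, names=names)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "cohort.csv")
    return table
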