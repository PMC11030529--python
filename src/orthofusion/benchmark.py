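"""End-to-end phantom benchmark: HR -> {Clin, RS, SR} -> all metrics.

For each seed the pipeline generates a high-resolution (HR) two-body
phantom, simulates three orthogonal thick-slice clinical volumes (Clin),
reslices the axial Clin back to fine spacing with Lanczos interpolation
(RS), and fuses the three Clin volumes into the super-resolution volume
(SR).  Each case is then scored against HR:

* image similarity — masked and whole-volume SSIM statistics and PSNR,
  computed after resampling the case onto the HR grid (SSIM needs a common
  lattice; linear resampling by default);
* morphology — marching-cubes bone surfaces at a fixed threshold, signed
  case-to-reference distances, summarized as bias / precision / MAE.

Reports carry full provenance (config hash, seed) so a run is reproducible
from its configuration alone.  Across-seed aggregation uses medians — the
study-level statistics are per-case orderings, not inferential tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .degrade import DegradeSpec, make_orthogonal_clinical_set, reslice_lanczos
from .fusion import FusionConfig, orthofuse
from .grid import BoneMask, VoxelGrid, Volume, resample
from .image_metrics import SimilarityReport, SSIMParams, masked_ssim_stats, psnr, ssim_map
from .morphology import (
    DistanceSummary,
    distance_summary,
    extract_isosurface,
    signed_distances,
    write_mesh,
)
from .phantom import PhantomSpec, make_phantom, mask_to_dilated_eval_mask, two_body_spec

__all__ = ["BenchmarkConfig", "CaseReport", "run_benchmark", "summarize_reports"]

CASES = ("Clin", "RS", "SR")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study configuration: phantom, degradation, fusion and metric settings."""

    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    grid_spacing: float = 0.6
    gap: float = 1.2
    noise_sigma: float = 25.0
    supersample: int = 3
    degrade: DegradeSpec = field(default_factory=lambda: DegradeSpec(through_axis=2))
    fusion: FusionConfig = field(default_factory=lambda: FusionConfig(target_spacing=0.3))
    ssim: SSIMParams = field(default_factory=SSIMParams)
    mask_margin_mm: float = 1.2
    iso_level: float | None = None  # None: midway background/trabecular HU
    mesh_samples: int | None = 3000
    out_dir: str | None = None

    def __post_init__(self):
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")

    def phantom_spec(self, seed: int) -> PhantomSpec:
        return two_body_spec(
            grid=VoxelGrid(self.grid_shape, (self.grid_spacing,) * 3),
            gap=self.gap,
            noise_sigma=self.noise_sigma,
            seed=seed,
            supersample=self.supersample,
        )

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (tuple, list)):
                return [encode(x) for x in obj]
            return obj

        payload = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CaseReport:
    """All metrics of one case volume against HR, for one phantom seed."""

    case: str
    seed: int
    similarity: SimilarityReport
    morphology: DistanceSummary
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "seed": self.seed,
            **self.similarity.to_dict(),
            **self.morphology.to_dict(),
            "provenance": self.provenance,
        }


class BenchmarkStageError(RuntimeError):
    """Wraps a failure with the pipeline stage and seed where it happened."""


def _stage(label: str, seed: int, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise BenchmarkStageError(f"stage {label!r} failed for seed {seed}: {exc}") from exc


def _image_report(
    label: str, case: Volume, hr: Volume, mask: BoneMask, params: SSIMParams
) -> SimilarityReport:
    on_hr, _ = resample(case, hr.grid)
    L = params.dynamic_range
    if L is None:
        L = float(hr.values.max() - hr.values.min())
    p = replace(params, dynamic_range=L)
    smap = ssim_map(on_hr, hr, p)
    mean_m, std_m = masked_ssim_stats(smap, mask)
    mean_w, std_w = masked_ssim_stats(smap, None)
    return SimilarityReport(
        case=label,
        ssim_mean_masked=mean_m,
        ssim_std_masked=std_m,
        ssim_mean_whole=mean_w,
        ssim_std_whole=std_w,
        psnr_db=psnr(on_hr, hr, L),
    )


def run_benchmark(config: BenchmarkConfig = BenchmarkConfig()) -> list[CaseReport]:
    """Run the full phantom study; returns one CaseReport per case per seed."""
    reports: list[CaseReport] = []
    out = config.out_dir
    if out:
        for sub in ("cases", "meshes", "reports"):
            os.makedirs(os.path.join(out, sub), exist_ok=True)
    for seed in config.seeds:
        spec = config.phantom_spec(seed)
        hr, masks, _ = _stage("phantom", seed, make_phantom, spec)
        clins = _stage("degrade", seed, make_orthogonal_clinical_set, hr, config.degrade)
        axial = clins[config.degrade.through_axis]
        rs = _stage("reslice", seed, reslice_lanczos, axial, config.degrade)
        sr = _stage("fuse", seed, orthofuse, clins, config.fusion).volume
        cases = {"Clin": axial, "RS": rs, "SR": sr}

        union = np.zeros(hr.grid.shape, dtype=np.uint8)
        for m in masks:
            union |= m.values
        eval_mask = mask_to_dilated_eval_mask(
            BoneMask(hr.grid, union), config.mask_margin_mm
        )
        bg, trab, _ = spec.intensities
        level = config.iso_level if config.iso_level is not None else (bg + trab) / 2.0
        ref_mesh = _stage("isosurface", seed, extract_isosurface, hr, level)

        provenance = {
            "config_hash": config.config_hash(),
            "seed": seed,
            "iso_level": level,
        }
        for label, vol in cases.items():
            sim = _stage(
                f"image-metrics[{label}]", seed,
                _image_report, label, vol, hr, eval_mask, config.ssim,
            )
            mesh = _stage(f"isosurface[{label}]", seed, extract_isosurface, vol, level)
            dists = _stage(
                f"distances[{label}]", seed,
                signed_distances, mesh, ref_mesh, config.mesh_samples, seed,
            )
            summary = distance_summary(dists)
            report = CaseReport(label, seed, sim, summary, provenance)
            reports.append(report)
            if out:
                from . import volio

                volio.write_volume(
                    vol, os.path.join(out, "cases", f"seed{seed}_{label}.nii.gz")
                )
                write_mesh(mesh, os.path.join(out, "meshes", f"seed{seed}_{label}.stl"))
                with open(
                    os.path.join(out, "reports", f"seed{seed}_{label}.json"), "w"
                ) as fh:
                    json.dump(report.to_dict(), fh, indent=2)
        if out:
            volio.write_volume(hr, os.path.join(out, "cases", f"seed{seed}_HR.nii.gz"))
            write_mesh(ref_mesh, os.path.join(out, "meshes", f"seed{seed}_HR.stl"))
    if out:
        summarize_reports(reports).to_csv(os.path.join(out, "summary.csv"))
    return reports


def summarize_reports(reports: list[CaseReport]) -> pd.DataFrame:
    """Across-seed median and IQR of every metric, indexed by case."""
    df = pd.DataFrame([r.to_dict() for r in reports]).drop(columns=["provenance"])
    metrics = [c for c in df.columns if c not in ("case", "seed")]
    med = df.groupby("case")[metrics].median()
    q1 = df.groupby("case")[metrics].quantile(0.25)
    q3 = df.groupby("case")[metrics].quantile(0.75)
    iqr = (q3 - q1).add_suffix("_iqr")
    return med.join(iqr).loc[list(CASES)]
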