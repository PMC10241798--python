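"""End-to-end orchestration: phantoms -> delineation -> features -> statistics.

The feature-extraction code path is a single function applied identically to
both timepoints (the timepoint is data, not code), guaranteeing pre/post
symmetry of the analysis settings.  Every analysis knob that clinical
delineation software leaves unreported (threshold fraction, gray-level
count, GLCM direction mode, entropy bins, recurrence coding, alpha) is
surfaced in :class:`PipelineConfig` so sensitivity analyses are scripted
rather than hacked.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import AnalysisReport, StatsConfig, run_cohort_analysis
from .errors import ConfigError, DataError, DegenerateInputError
from .first_order import (
    excess_kurtosis,
    metabolic_features,
    shannon_entropy,
    skewness,
)
from .glcm import texture_pipeline
from .io import SUVVolume, read_clinical_table, read_volume, write_feature_table
from .phantom import CohortBundle, CohortSpec, PlantedEffect, generate_cohort
from .segmentation import BoundingBox, VOIMask, delineate_tumor

__all__ = [
    "PipelineConfig",
    "extract_features",
    "extract_bundle",
    "extract_directory",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of the whole pipeline."""

    threshold_fraction: float = 0.35
    glcm_levels: int = 8
    glcm_mode: str = "3d"  # "3d" | "2d-axial"
    entropy_bins: int = 64
    recurrence_coding: str = "binary"
    group_variable: str = "recurrence"
    alpha: float = 0.05
    seed: int = 0
    n_patients: int = 30  # used only when simulating
    planted_effects: list = field(default_factory=list)
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ConfigError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.glcm_levels < 2:
            raise ConfigError(f"glcm_levels must be >= 2, got {self.glcm_levels}")
        if self.glcm_mode not in ("3d", "2d-axial"):
            raise ConfigError(f"unknown glcm_mode {self.glcm_mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.entropy_bins < 1:
            raise ConfigError(f"entropy_bins must be >= 1, got {self.entropy_bins}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stats_config(self) -> StatsConfig:
        return StatsConfig(
            alpha=self.alpha,
            recurrence_coding=self.recurrence_coding,
            group_variable=self.group_variable,
        )


def extract_features(
    vol: SUVVolume,
    search_region: BoundingBox | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Delineate one volume and compute the full feature record.

    Returns a flat dict of metabolic, first-order and GLCM features, plus
    the discretization settings used (so the table documents its own
    configuration).
    """
    cfg = config or PipelineConfig()
    mask = delineate_tumor(vol, search_region, fraction=cfg.threshold_fraction)
    met = metabolic_features(vol, mask)
    x = vol.values[mask.mask]
    try:
        ske = skewness(x)
        kurt = excess_kurtosis(x)
    except DegenerateInputError:
        ske = float("nan")
        kurt = float("nan")
    ent = shannon_entropy(x, n_bins=cfg.entropy_bins)
    tex = texture_pipeline(vol, mask, n_levels=cfg.glcm_levels, mode=cfg.glcm_mode)
    return dict(
        suv_max=met.suv_max,
        suv_mean=met.suv_mean,
        suv_sd=met.suv_sd,
        cov=met.cov,
        mtv_cm3=met.mtv_cm3,
        tlg=met.tlg,
        asp=met.asp,
        skewness=ske,
        kurtosis=kurt,
        entropy_bits=ent,
        glcm_contrast=tex.contrast,
        glcm_correlation=tex.correlation,
        glcm_energy=tex.energy,
        glcm_homogeneity=tex.homogeneity,
        glcm_levels=cfg.glcm_levels,
        glcm_mode=cfg.glcm_mode,
    )


def _truth_search_region(mask: VOIMask, margin: int = 3) -> BoundingBox:
    return mask.bounding_box(margin=margin)


def extract_bundle(
    bundle: CohortBundle, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Feature table for an in-memory phantom cohort.

    The search region for each lesion is the ground-truth bounding box plus
    a margin, standing in for the operator's lesion selection.
    """
    cfg = config or PipelineConfig()
    rows = []
    for p in bundle.patients:
        for tp, vol, truth in (
            ("pre", p.pre, p.pre_truth),
            ("post", p.post, p.post_truth),
        ):
            rec = extract_features(vol, _truth_search_region(truth.true_mask), cfg)
            rows.append(dict(patient_id=p.patient_id, timepoint=tp, **rec))
    return pd.DataFrame(rows)


def extract_directory(
    input_dir: str | Path, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Feature table for a directory of paired ``{pid}_pre/post.nii.gz`` volumes.

    When ``{pid}_{tp}_truthmask.nii.gz`` exists its bounding box (plus
    margin) seeds the lesion search; otherwise the whole grid is searched.
    Unpaired volumes fail fast with an itemized message.
    """
    cfg = config or PipelineConfig()
    d = Path(input_dir)
    if not d.is_dir():
        raise DataError(f"input directory not found: {d}")
    pres = {f.name[: -len("_pre.nii.gz")] for f in d.glob("*_pre.nii.gz")}
    posts = {f.name[: -len("_post.nii.gz")] for f in d.glob("*_post.nii.gz")}
    if pres != posts:
        raise DataError(
            "mismatched volume pairs; missing post for "
            f"{sorted(pres - posts)}, missing pre for {sorted(posts - pres)}"
        )
    if not pres:
        raise DataError(f"no {{pid}}_pre.nii.gz volumes found in {d}")
    rows = []
    for pid in sorted(pres):
        for tp in ("pre", "post"):
            vol = read_volume(d / f"{pid}_{tp}.nii.gz", units="suv")
            mask_path = d / f"{pid}_{tp}_truthmask.nii.gz"
            region = None
            if mask_path.exists():
                mvol = read_volume(mask_path, units="suv")
                region = _truth_search_region(
                    VOIMask(mvol.values > 0.5, mvol.voxel_spacing)
                )
            rec = extract_features(vol, region, cfg)
            rows.append(dict(patient_id=pid, timepoint=tp, **rec))
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> AnalysisReport:
    """Run the full pipeline per configuration.

    With no ``input_dir``, a phantom cohort of ``n_patients`` is simulated
    under ``seed`` (and written to ``output_dir/volumes`` when an output
    directory is configured).  Features are extracted with identical
    settings for both timepoints, the statistics layer is run, and — when
    ``output_dir`` is set — the feature table, report tables and a
    provenance block (config hash, seed, versions) are written to disk.
    """
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if cfg.input_dir is None:
        cspec = CohortSpec(
            n_patients=cfg.n_patients,
            seed=cfg.seed,
            planted_effects=tuple(PlantedEffect(*e) for e in cfg.planted_effects),
        )
        vol_dir = out / "volumes" if out else None
        bundle = generate_cohort(cspec, out_dir=vol_dir)
        features = extract_bundle(bundle, cfg)
        clinical = bundle.clinical
    else:
        features = extract_directory(cfg.input_dir, cfg)
        clinical = read_clinical_table(Path(cfg.input_dir) / "clinical.csv")
    report = run_cohort_analysis(features, clinical, cfg.stats_config())
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(features, out / "features.csv")
        clinical.to_csv(out / "clinical.csv", index=False)
        report.to_dir(out / "report")
        provenance = dict(
            config=cfg.to_dict(),
            config_hash=cfg.content_hash(),
            seed=cfg.seed,
            versions=dict(
                petromics=__version__,
                numpy=np.__version__,
                pandas=pd.__version__,
            ),
        )
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return report
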