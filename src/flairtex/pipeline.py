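"""End-to-end pipeline driver: simulate -> preprocess -> segment -> texture
-> layers -> extract -> stats, with a JSON run manifest.

The library entry points are :func:`process_subject` (one subject's volumes
to one feature row) and :func:`build_cohort_table` (an in-memory cohort to
the tidy table the statistics battery consumes).  :func:`run_pipeline` is
the disk-based orchestrator behind the CLI: it walks ``sub-*`` directories,
is resumable per subject (a subject with an existing ``features.json`` is
not recomputed), isolates per-subject failures, and writes a manifest with
a config hash and output checksums so identical runs are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .layers import build_layers, extract_layer_features
from .masks import build_nawm, segment_wmh, summarize_volumes
from .preprocessing import correct_bias, estimate_bias_field, \
    normalize_intensities
from .stats import run_model_battery
from .texture import extract_roi_features, make_texture_maps, quantize, \
    transform_features
from .volumes import ImageVolume, MaskVolume, read_image, read_mask

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "process_subject",
           "build_cohort_table", "run_pipeline"]

__version__ = "0.1.0"


@dataclasses.dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run; JSON round-trippable."""

    input_dir: str = "."
    output_dir: str = "out"
    n_levels: int = 8
    wmh_k: float = 1.2
    min_lesion_voxels: int = 1
    bias_degree: int = 2
    skip_bias: bool = False
    n_layers: int = 10
    layer_increment: int = 2
    fdr_q: float = 0.05
    seed: int = 0
    simulate: bool = False
    n_subjects: int = 10
    resume: bool = True
    run_stats: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    subject_status: dict[str, str]
    checksums: dict[str, str]
    warnings: list[str]

    @property
    def n_failed(self) -> int:
        return sum(1 for s in self.subject_status.values()
                   if s.startswith("failed"))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def process_subject(img: ImageVolume, brain: MaskVolume, wm: MaskVolume,
                    etiv_mm3: float, *, n_levels: int = 8, wmh_k: float = 1.2,
                    min_lesion_voxels: int = 1, bias_degree: int = 2,
                    skip_bias: bool = False, n_layers: int = 10,
                    layer_increment: int = 2, compute_layers: bool = True
                    ) -> tuple[dict[str, float], dict]:
    """Full single-subject feature extraction.

    Returns ``(features, artifacts)``: a flat feature dict (cube-root
    transformed texture values with ``_raw`` companions, plus the
    normalized WMH volume) and the intermediate volumes/masks for
    inspection or serialization.
    """
    if skip_bias:
        corrected = img
    else:
        # fit the shading polynomial within WM (a homogeneous class);
        # hyperintense lesion voxels are MAD-trimmed inside the estimator
        field = estimate_bias_field(img, wm, bias_degree)
        corrected = correct_bias(img, field)
    norm = normalize_intensities(corrected)
    wmh = segment_wmh(corrected, brain, wm, k=wmh_k,
                      min_size_voxels=min_lesion_voxels)
    nawm = build_nawm(wm, wmh)
    q = quantize(corrected, brain, n_levels)
    maps = make_texture_maps(q)

    features: dict[str, float] = {}
    for prefix, roi in (("WMHT", wmh), ("NAWMT", nawm)):
        feats = transform_features(extract_roi_features(norm, maps, roi))
        features.update({f"{prefix}_{k}": v for k, v in feats.items()})
    layerset = None
    if compute_layers:
        layerset = build_layers(wmh, wm, n_layers, layer_increment)
        lf = extract_layer_features(norm, maps, layerset)
        features.update({k: float(np.cbrt(v)) for k, v in lf.items()})
    summary = summarize_volumes(wmh, etiv_mm3)
    features["wmh_volume_mm3"] = summary.wmh_volume_mm3
    features["wmh_pct_etiv"] = summary.wmh_pct_etiv
    features["wmh_pct_etiv_cuberoot"] = summary.wmh_pct_etiv_cuberoot

    artifacts = {"corrected": corrected, "normalized": norm, "wmh": wmh,
                 "nawm": nawm, "quantized": q, "maps": maps,
                 "layers": layerset}
    return features, artifacts


def build_cohort_table(cohort: "synthetic.CohortResult", *,
                       compute_layers: bool = True,
                       **kwargs) -> pd.DataFrame:
    """Process every subject of an in-memory cohort into one tidy table."""
    rows = []
    for sub in cohort.subjects:
        etiv = float(cohort.covariates.set_index("subject_id")
                     .loc[sub.subject_id, "etiv_mm3"])
        feats, _ = process_subject(sub.image, sub.masks["brain"],
                                   sub.masks["wm"], etiv,
                                   compute_layers=compute_layers, **kwargs)
        rows.append({"subject_id": sub.subject_id, **feats})
    table = pd.DataFrame(rows)
    return table.merge(cohort.covariates, on="subject_id", validate="1:1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Disk-based end-to-end run over ``sub-*`` directories."""
    from .volumes import write_mask

    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())
    warnings: list[str] = []

    if config.simulate:
        spec = synthetic.PhantomSpec(rng_seed=config.seed)
        cohort = synthetic.CohortSpec(n_subjects=config.n_subjects,
                                      rng_seed=config.seed)
        if not (in_dir / "covariates.csv").exists():
            synthetic.write_cohort(synthetic.generate_cohort(spec, cohort),
                                   in_dir)

    covars = pd.read_csv(in_dir / "covariates.csv").set_index("subject_id")
    status: dict[str, str] = {}
    checks: dict[str, str] = {}
    rows: list[dict] = []
    for sub_dir in sorted(in_dir.glob("sub-*")):
        sid = sub_dir.name
        feat_path = out_dir / sid / "features.json"
        try:
            if config.resume and feat_path.exists():
                rows.append({"subject_id": sid,
                             **json.loads(feat_path.read_text())})
                status[sid] = "cached"
                checks[f"{sid}/features.json"] = _sha256(feat_path)
                continue
            img = read_image(sub_dir / "flair.nii.gz")
            brain = read_mask(sub_dir / "brain.nii.gz", "brain")
            wm = read_mask(sub_dir / "wm.nii.gz", "wm")
            feats, artifacts = process_subject(
                img, brain, wm, float(covars.loc[sid, "etiv_mm3"]),
                n_levels=config.n_levels, wmh_k=config.wmh_k,
                min_lesion_voxels=config.min_lesion_voxels,
                bias_degree=config.bias_degree, skip_bias=config.skip_bias,
                n_layers=config.n_layers,
                layer_increment=config.layer_increment)
            feat_path.parent.mkdir(parents=True, exist_ok=True)
            feat_path.write_text(json.dumps(feats, sort_keys=True))
            write_mask(artifacts["wmh"], feat_path.parent / "wmh.nii.gz")
            write_mask(artifacts["nawm"], feat_path.parent / "nawm.nii.gz")
            rows.append({"subject_id": sid, **feats})
            status[sid] = "ok"
            checks[f"{sid}/features.json"] = _sha256(feat_path)
        except Exception as exc:  # isolate per-subject failures
            logger.exception("subject %s failed", sid)
            status[sid] = f"failed: {exc}"

    if rows:
        table = pd.DataFrame(rows).merge(covars.reset_index(),
                                         on="subject_id", how="left")
        table.to_csv(out_dir / "features.csv", index=False)
        checks["features.csv"] = _sha256(out_dir / "features.csv")
        if config.run_stats:
            try:
                res = run_model_battery(table, fdr_q=config.fdr_q,
                                       n_layers=config.n_layers)
                res.results.to_csv(out_dir / "results.csv", index=False)
                checks["results.csv"] = _sha256(out_dir / "results.csv")
            except ValueError as exc:
                warnings.append(f"statistics battery skipped: {exc}")

    manifest = RunManifest(__version__, config.config_hash, status, checks,
                           warnings)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
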