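"""End-to-end pipeline driver: simulation -> segmentation -> crops ->
depletion -> contrastive training -> feature extraction -> benchmarks.

Each enabled stage reads only earlier stages' directories, writes its own
write-once directory under the run root and records input/output checksums
in ``manifest.json`` (config hash, seeds, package version, per-stage
artifacts).  A rerun with an identical config and seed reproduces identical
checksums for the deterministic stages; completed stages are skipped, so a
failed run resumes at the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import io as lio
from .benchmarks import linear_probe
from .contrastive import AugmentationConfig, ContrastiveEncoder, EncoderConfig, train_encoder
from .depletion import DepletionConfig, deplete, train_depletion
from .features import engineered_features_batch
from .outliers import detect_outliers, topk_recovery
from .segmentation import extract_crop, match_instances, f1_at_iou, reference_segment
from .synthetic import generate_crop_dataset, generate_slide
from .types import (
    RARE_PHENOTYPES,
    WBC_PHENOTYPES,
    LbxError,
    SlideConfig,
)

log = logging.getLogger("lbxpheno")

_STAGES = ("simulate", "segment", "crops", "deplete", "train_encoder", "extract", "benchmark")


@dataclass
class PipelineConfig:
    """Configuration of a full desk-scale run."""

    out_dir: str = "run"
    seed: int = 0
    profile: str = "desk"
    stages: Sequence[str] = _STAGES
    n_cells: int = 2000
    n_frames: int = 4
    frame_shape: tuple = (502, 681)
    rarity: Mapping[str, float] = field(
        default_factory=lambda: {p: 0.01 for p in RARE_PHENOTYPES}
    )
    crops_per_class: int = 150
    encoder_epochs: int | None = None
    keep_threshold: float = 0.5

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise LbxError(f"unknown stages {sorted(unknown)}")
        if self.profile not in ("desk", "paper"):
            raise LbxError("profile must be desk or paper")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dir_checksums(d: Path) -> Dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(d.rglob("*")) if p.is_file()}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest_path = root / "manifest.json"
    manifest = {
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest["stages"] = old.get("stages", {})

    def done(stage: str) -> bool:
        return manifest["stages"].get(stage, {}).get("complete", False)

    def finish(stage: str, out: Path, t0: float, **extra):
        manifest["stages"][stage] = {
            "complete": True,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": _dir_checksums(out),
            **extra,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        log.info("stage %s finished in %.1fs", stage, time.time() - t0)

    def run_stage(stage, fn):
        if stage not in config.stages or done(stage):
            return
        t0 = time.time()
        out = root / stage
        out.mkdir(exist_ok=True)
        try:
            extra = fn(out) or {}
        except Exception as e:
            raise LbxError(f"stage {stage!r} failed: {e}") from e
        finish(stage, out, t0, **extra)

    # ---- simulate --------------------------------------------------------
    def _simulate(out: Path):
        sc = SlideConfig(
            n_frames=config.n_frames,
            frame_shape=tuple(config.frame_shape),
            n_cells=config.n_cells,
            rarity=dict(config.rarity),
            seed=config.seed,
        )
        frames, masks, truth = generate_slide(sc)
        lio.write_frames(frames, out / "frames")
        lio.write_masks(masks, out / "masks")
        lio.write_truth(truth, out / "truth.csv")
        return {"n_cells": len(truth)}

    run_stage("simulate", _simulate)

    # ---- segment ---------------------------------------------------------
    def _segment(out: Path):
        frames_dir = root / "simulate" / "frames"
        if not frames_dir.exists():
            raise LbxError("missing input directory simulate/frames")
        frames = lio.read_frames(frames_dir)
        gt_masks = lio.read_masks(root / "simulate" / "masks")
        preds = [reference_segment(f) for f in frames]
        lio.write_masks(preds, out / "masks")
        f1s = []
        for gt, pr in zip(gt_masks, preds):
            f1s.append(f1_at_iou(match_instances(gt, pr, 0.5)))
        pd.DataFrame({"frame": range(len(f1s)), "f1_at_0.5": f1s}).to_csv(
            out / "segmentation_eval.csv", index=False
        )
        return {"mean_f1_at_0.5": float(np.mean(f1s))}

    run_stage("segment", _segment)

    # ---- crops -----------------------------------------------------------
    def _crops(out: Path):
        frames = lio.read_frames(root / "simulate" / "frames")
        masks = lio.read_masks(root / "simulate" / "masks")
        truth = lio.read_truth(root / "simulate" / "truth.csv").table
        crops, rows = [], []
        for _, rec in truth.iterrows():
            fi, cid = int(rec["frame"]), int(rec["cell_id"])
            crops.append(extract_crop(frames[fi], masks[fi], cid).data)
            rows.append(
                dict(crop_id=cid, slide=0, frame=fi, cell_id=cid, label=rec["phenotype"])
            )
        lio.write_crops(np.stack(crops), pd.DataFrame(rows), out)
        return {"n_crops": len(crops)}

    run_stage("crops", _crops)

    # ---- deplete ---------------------------------------------------------
    def _deplete(out: Path):
        crops, index = lio.read_crops(root / "crops")
        y = index["label"].isin(WBC_PHENOTYPES).to_numpy().astype(int)
        dcfg = DepletionConfig(epochs=5 if config.profile == "desk" else 25)
        model, trace = train_depletion(crops, y, dcfg, seed=config.seed)
        kept, removed = deplete(crops, model, config.keep_threshold)
        index.iloc[kept].to_csv(out / "kept_index.csv", index=False)
        pd.DataFrame(trace).to_csv(out / "loss_trace.csv", index=False)
        return {"kept": int(len(kept)), "removed": int(len(removed))}

    run_stage("deplete", _deplete)

    # ---- train encoder ---------------------------------------------------
    def _train(out: Path):
        crops, labels = generate_crop_dataset(
            config.crops_per_class, seed=config.seed
        )
        ecfg = (
            EncoderConfig.paper()
            if config.profile == "paper"
            else EncoderConfig.desk()
        )
        if config.encoder_epochs is not None:
            ecfg.epochs = config.encoder_epochs
        model, trace = train_encoder(crops, ecfg, AugmentationConfig(), seed=config.seed)
        model.save(out / "encoder.npz")
        pd.DataFrame({"epoch": range(len(trace)), "loss": trace}).to_csv(
            out / "loss_trace.csv", index=False
        )
        return {"final_loss": trace[-1]}

    run_stage("train_encoder", _train)

    # ---- extract ---------------------------------------------------------
    def _extract(out: Path):
        crops, index = lio.read_crops(root / "crops")
        model = ContrastiveEncoder.load(root / "train_encoder" / "encoder.npz")
        learned = model.encode(crops)
        learned.ids = index["crop_id"].to_numpy()
        lio.write_features(learned, out / "learned.parquet")
        eng = engineered_features_batch(crops)
        eng.ids = index["crop_id"].to_numpy()
        lio.write_features(eng, out / "engineered.parquet")
        lio.write_manifest_csv(out / "engineered_manifest.csv")
        return {"n": len(learned)}

    run_stage("extract", _extract)

    # ---- benchmark -------------------------------------------------------
    def _benchmark(out: Path):
        crops, index = lio.read_crops(root / "crops")
        labels = index["label"].to_numpy()
        learned = lio.read_features(root / "extract" / "learned.parquet")
        eng = lio.read_features(root / "extract" / "engineered.parquet")
        summary = {}
        counts = pd.Series(labels).value_counts()
        ok = np.isin(labels, counts[counts >= 5].index.to_numpy())
        for name, feats in (("learned", learned), ("engineered", eng)):
            pr = linear_probe(feats.values[ok], labels[ok], split_seed=config.seed)
            summary[f"probe_accuracy_{name}"] = pr.accuracy
        is_rare = np.isin(labels, RARE_PHENOTYPES)
        if is_rare.any() and (~is_rare).any():
            for name, feats in (("learned", learned), ("engineered", eng)):
                rk = detect_outliers(feats.values, "COPOD", seed=config.seed)
                k = max(1, int(0.05 * len(labels)))
                _, auc = topk_recovery(rk, is_rare, k)
                summary[f"outlier_copod_auc_{name}"] = auc
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary

    run_stage("benchmark", _benchmark)

    return root
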