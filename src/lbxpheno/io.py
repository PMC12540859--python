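"""File-format adapters: TIFF frames and masks, crop stacks, feature tables.

Conventions
-----------
* frames: one 16-bit grayscale TIFF per channel per frame, named
  ``{frame:04d}_{DAPI|CK|VIM|CD45CD31}.tif``;
* masks: 32-bit integer label TIFF, ``{frame:04d}_mask.tif``;
* crops: 5-page multi-page TIFF per crop (+ CSV index
  ``crop_id,slide,frame,cell_id,label``);
* features: parquet/CSV tables with a ``crop_id`` column plus one named
  column per feature;
* slide truth: CSV with header ``cell_id,frame,row,col,phenotype,area``.

Round trips are bit-exact for integer artifacts and within 1e-7 for reals.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .types import (
    CHANNEL_SLUGS,
    SPACE_ENGINEERED,
    SPACE_LEARNED,
    CellCrop,
    FeatureMatrix,
    IFFrame,
    InstanceMask,
    LbxError,
    SlideTruth,
    TRUTH_COLUMNS,
)


def write_frames(frames: Sequence[IFFrame], out_dir: str | Path) -> List[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for fi, frame in enumerate(frames):
        for ci, slug in enumerate(CHANNEL_SLUGS):
            p = out / f"{fi:04d}_{slug}.tif"
            tifffile.imwrite(p, frame.channels[ci].astype(np.uint16))
            paths.append(p)
    return paths


_FRAME_RE = re.compile(r"^(\d{4})_(DAPI|CK|VIM|CD45CD31)\.tif$")


def read_frames(in_dir: str | Path) -> List[IFFrame]:
    """Load all frames from a directory of per-channel TIFFs.

    Every frame must provide all four channels; a partial channel set is a
    malformed input and raises.
    """
    files: Dict[int, Dict[str, Path]] = {}
    for p in sorted(Path(in_dir).iterdir()):
        m = _FRAME_RE.match(p.name)
        if m:
            files.setdefault(int(m.group(1)), {})[m.group(2)] = p
    if not files:
        raise LbxError(f"no frame TIFFs found in {in_dir}")
    frames = []
    for fi in sorted(files):
        chans = files[fi]
        missing = [s for s in CHANNEL_SLUGS if s not in chans]
        if missing:
            raise LbxError(f"frame {fi}: missing channel files {missing}")
        planes = [tifffile.imread(chans[s]) for s in CHANNEL_SLUGS]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise LbxError(f"frame {fi}: channel shapes differ: {shapes}")
        frames.append(IFFrame(np.stack(planes)))
    return frames


def write_masks(masks: Sequence[InstanceMask], out_dir: str | Path) -> List[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for fi, mask in enumerate(masks):
        p = out / f"{fi:04d}_mask.tif"
        tifffile.imwrite(p, mask.labels.astype(np.int32))
        paths.append(p)
    return paths


def read_masks(in_dir: str | Path) -> List[InstanceMask]:
    paths = sorted(Path(in_dir).glob("*_mask.tif"))
    if not paths:
        raise LbxError(f"no mask TIFFs found in {in_dir}")
    return [InstanceMask(tifffile.imread(p).astype(np.int32)) for p in paths]


def write_truth(truth: SlideTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.table.to_csv(path, index=False, columns=list(TRUTH_COLUMNS))
    return path


def read_truth(path: str | Path) -> SlideTruth:
    df = pd.read_csv(path)
    return SlideTruth(df)


def write_crops(
    crops: np.ndarray | Sequence[CellCrop],
    index: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write crops as 5-page TIFFs plus a CSV index.

    ``index`` must carry columns ``crop_id, slide, frame, cell_id, label``
    aligned with ``crops``.
    """
    need = ["crop_id", "slide", "frame", "cell_id", "label"]
    missing = [c for c in need if c not in index.columns]
    if missing:
        raise LbxError(f"crop index missing columns {missing}")
    if index["crop_id"].duplicated().any():
        raise LbxError("duplicate crop ids in index")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrs = [c.data if isinstance(c, CellCrop) else np.asarray(c) for c in crops]
    if len(arrs) != len(index):
        raise LbxError("crops/index length mismatch")
    for arr, cid in zip(arrs, index["crop_id"]):
        tifffile.imwrite(out / f"crop_{int(cid):06d}.tif", arr.astype(np.uint16))
    index[need].to_csv(out / "index.csv", index=False)
    return out


def read_crops(in_dir: str | Path) -> Tuple[np.ndarray, pd.DataFrame]:
    in_dir = Path(in_dir)
    index = pd.read_csv(in_dir / "index.csv")
    arrs = [
        tifffile.imread(in_dir / f"crop_{int(cid):06d}.tif")
        for cid in index["crop_id"]
    ]
    return np.stack(arrs), index


def write_features(features: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = features.to_frame()
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        df.to_parquet(path, index=False)
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path) if path.suffix == ".csv" else pd.read_parquet(path)
    if "crop_id" not in df.columns:
        raise LbxError("feature table lacks a crop_id column")
    vals = df.drop(columns=["crop_id"]).to_numpy(dtype=float)
    names = [c for c in df.columns if c != "crop_id"]
    space = SPACE_ENGINEERED if vals.shape[1] == 368 else SPACE_LEARNED
    return FeatureMatrix(
        vals,
        space=space,
        names=names if space == SPACE_ENGINEERED else None,
        ids=df["crop_id"].to_numpy(),
    )


def write_manifest_csv(path: str | Path) -> Path:
    """Write the frozen engineered-368 feature-name manifest."""
    from .features import feature_names

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"index": range(368), "feature": feature_names()}
    ).to_csv(path, index=False)
    return path
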