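"""Core value types shared across the pipeline.

The unit of analysis is a single nucleated cell imaged in four co-registered
immunofluorescence (IF) channels — DAPI (nuclear stain), pan-cytokeratin (CK),
vimentin (VIM) and a multiplexed CD45/CD31 leukocyte/endothelial channel —
plus the binary instance mask of that cell.  Every feature extractor in the
package consumes the same 75x75x5 crop layout (4 IF channels + mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

#: IF channel identities, in storage order.
CHANNELS: Tuple[str, ...] = ("DAPI", "CK", "VIM", "CD45/31")

#: Filename-safe aliases for the channels (the multiplexed channel has a "/").
CHANNEL_SLUGS: Tuple[str, ...] = ("DAPI", "CK", "VIM", "CD45CD31")

#: The ten cell phenotypes scored in IF space.  The first seven are the rare,
#: tumor- or vasculature-associated classes; the last three are the common
#: white-blood-cell (WBC) subclasses that dominate enrichment-free slides.
PHENOTYPES: Tuple[str, ...] = (
    "CTC",
    "imCTC",
    "pcCTC",
    "CEC",
    "Mega-like",
    "Fibro-like",
    "L-Nuclei",
    "Lymph",
    "Mono",
    "Gran",
)

RARE_PHENOTYPES: Tuple[str, ...] = PHENOTYPES[:7]
WBC_PHENOTYPES: Tuple[str, ...] = PHENOTYPES[7:]

#: Side length of a single-cell crop, and the index of its center pixel.
CROP_SIZE: int = 75
CROP_CENTER: int = CROP_SIZE // 2

#: Intensity ceiling of the 16-bit scanner range.
UINT16_MAX: int = 65535

#: Default frame dimensions (rows, cols) of one scanner field of view.
FRAME_SHAPE: Tuple[int, int] = (1004, 1362)


class LbxError(ValueError):
    """Base error for invalid inputs to pipeline operations."""


@dataclass
class IFFrame:
    """One scanner frame: four co-registered 16-bit intensity planes.

    Parameters
    ----------
    channels
        Array of shape ``(4, H, W)`` in the fixed channel order of
        :data:`CHANNELS`, values in ``[0, 65535]``.
    pixel_size
        Relative pixel scale (dimensionless, 1.0 = nominal).
    """

    channels: np.ndarray
    pixel_size: float = 1.0
    channel_names: Tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != len(self.channel_names):
            raise LbxError(
                f"frame must be (n_channels, H, W) with {len(self.channel_names)} "
                f"channels, got shape {self.channels.shape}"
            )
        if self.channels.size and (
            self.channels.min() < 0 or self.channels.max() > UINT16_MAX
        ):
            raise LbxError("frame intensities must lie in [0, 65535]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[self.channel_names.index(name)]
        except ValueError:
            raise LbxError(f"unknown channel {name!r}") from None


@dataclass
class InstanceMask:
    """Per-pixel integer cell labels aligned to an :class:`IFFrame`; 0 = background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise LbxError(f"mask must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise LbxError("mask labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise LbxError("mask labels must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of positive labels present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class CellCrop:
    """A 75x75x5 single-cell stack: 4 IF channels + binary center-cell mask.

    ``data`` has shape ``(5, 75, 75)`` (channels first).  Channel 5 is the
    indicator of the center cell only; neighbouring cells are zeroed there but
    their intensities remain in the IF channels.
    """

    data: np.ndarray
    cell_id: int = -1
    frame_index: int = -1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (5, CROP_SIZE, CROP_SIZE):
            raise LbxError(
                f"crop must be (5, {CROP_SIZE}, {CROP_SIZE}), got {self.data.shape}"
            )
        m = self.data[4]
        if not np.isin(np.unique(m), (0, 1)).all():
            raise LbxError("crop mask channel must be binary")

    @property
    def mask(self) -> np.ndarray:
        return self.data[4].astype(bool)

    @property
    def intensities(self) -> np.ndarray:
        """The 4 IF planes, shape (4, 75, 75)."""
        return self.data[:4]


#: Feature-space tags.
SPACE_ENGINEERED = "engineered-368"
SPACE_LEARNED = "learned-128"
_SPACE_DIMS = {SPACE_ENGINEERED: 368, SPACE_LEARNED: 128}


@dataclass
class FeatureMatrix:
    """A stack of per-cell feature vectors tagged with their feature space.

    ``values`` is ``(n_cells, dim)``; ``dim`` is enforced by the space tag
    (368 engineered, 128 learned).  ``names`` is required for the engineered
    space (the frozen manifest order) and absent for the learned space.
    """

    values: np.ndarray
    space: str
    names: Sequence[str] | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.space not in _SPACE_DIMS:
            raise LbxError(f"unknown feature space {self.space!r}")
        want = _SPACE_DIMS[self.space]
        if self.values.shape[1] != want:
            raise LbxError(
                f"{self.space} features must have {want} dims, got {self.values.shape[1]}"
            )
        if not np.isfinite(self.values).all():
            raise LbxError("feature values must be finite")
        if self.names is not None and len(self.names) != want:
            raise LbxError("feature-name manifest length mismatch")
        if self.ids is None:
            self.ids = np.arange(len(self.values))
        else:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != len(self.values):
                raise LbxError("ids/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        cols = (
            list(self.names)
            if self.names is not None
            else [f"f{i:03d}" for i in range(self.values.shape[1])]
        )
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "crop_id", self.ids)
        return df


TRUTH_COLUMNS = ("cell_id", "frame", "row", "col", "phenotype", "area")


@dataclass
class SlideTruth:
    """Ground-truth table for a synthetic slide: one row per rendered cell."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.table.columns]
        if missing:
            raise LbxError(f"truth table missing columns {missing}")
        if self.table["cell_id"].duplicated().any():
            raise LbxError("cell ids must be unique per slide")

    def __len__(self) -> int:
        return len(self.table)

    def counts(self) -> pd.Series:
        return self.table["phenotype"].value_counts()


@dataclass
class MarkerProfile:
    """Phenotype-conditional rendering parameters for the synthetic generator.

    ``expression`` maps each IF channel to a positive/negative state;
    ``log_intensity`` maps each channel to the (location, spread) of the
    natural-log intensity of that channel inside the cell footprint, on the
    16-bit scale.  Radii are in pixels.
    """

    phenotype: str
    expression: Mapping[str, bool]
    log_intensity: Mapping[str, Tuple[float, float]]
    nucleus_radius: Tuple[float, float]
    cytoplasm_radius: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise LbxError(f"unknown phenotype {self.phenotype!r}")
        if not self.expression.get("DAPI", False):
            raise LbxError("DAPI must be positive for every phenotype")
        for ch in CHANNELS:
            if ch not in self.expression or ch not in self.log_intensity:
                raise LbxError(f"profile missing channel {ch!r}")

    def positive_channels(self) -> Tuple[str, ...]:
        return tuple(ch for ch in CHANNELS if self.expression[ch])


@dataclass
class SlideConfig:
    """Configuration of one synthetic slide.

    ``rarity`` maps phenotype -> expected fraction of all cells; phenotypes
    not listed share the remainder among the WBC subclasses according to
    ``wbc_mix``.  The default rare fractions follow the 1:10,000 (0.01%)
    spike-in concentration of the contrived-slide design.
    """

    n_frames: int = 1
    frame_shape: Tuple[int, int] = FRAME_SHAPE
    n_cells: int = 2000
    rarity: Mapping[str, float] = field(
        default_factory=lambda: {p: 1e-4 for p in RARE_PHENOTYPES}
    )
    wbc_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Lymph": 0.30, "Mono": 0.08, "Gran": 0.62}
    )
    background_level: float = 900.0
    background_noise: float = 250.0
    blur_sigma_range: Tuple[float, float] = (0.0, 1.2)
    gain_range: Tuple[float, float] = (0.9, 1.1)
    pixel_size_jitter: float = 0.03
    artifacts: bool = True
    allow_clusters: bool = False
    min_margin: int = 12
    seed: int = 0
    exact_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        fr = np.array(list(self.rarity.values()), dtype=float)
        if len(fr) and (fr.min() < 0 or fr.max() > 1 or fr.sum() > 1):
            raise LbxError("rarity fractions must be in [0,1] and sum to <= 1")
        for p in self.rarity:
            if p not in PHENOTYPES:
                raise LbxError(f"unknown phenotype {p!r} in rarity map")
        if self.frame_shape[0] <= 0 or self.frame_shape[1] <= 0:
            raise LbxError("frame dimensions must be positive")
        if self.n_cells < 0 or self.n_frames <= 0:
            raise LbxError("cell and frame counts must be positive")
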