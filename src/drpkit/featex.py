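"""Feature extraction: tensor fusion, decimal scaling, texture descriptors,
and assembly of the full per-pair feature matrix.

Each cell line-drug pair is represented as a 224x224x3 tensor whose
channels are (tree-distance map, binary event-indicator map, drug
depiction). Deep features come from the decimal-scaled CNN in
:mod:`drpkit.dscnn`; handcrafted descriptors are GLCM/Haralick statistics,
uniform local binary patterns, and local tetra patterns; auxiliary
attributes (per-gene omics values, drug descriptors, target match) are
concatenated last. Continuous columns are standardized with training-fold
statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern

TENSOR_SIZE = 224
CHANNEL_ROLES = ("tree_map", "event_map", "depiction")

#: Block widths (deep, handcrafted, attributes) pinning the full
#: configuration to 2,378 columns.
PAPER_FAITHFUL_WIDTHS = (1024, 354, 1000)


# ---------------------------------------------------------------------------
# Decimal scaling
# ---------------------------------------------------------------------------


def ds_exponent(Z: np.ndarray) -> int:
    """Smallest nonnegative j with max|Z| / 10**j < 1 (0 for max|Z| < 1)."""
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("decimal scaling requires finite input")
    m = float(np.abs(Z).max()) if Z.size else 0.0
    j = 0
    while m / 10**j >= 1.0:
        j += 1
    return j


def ds_scale(Z: np.ndarray) -> np.ndarray:
    """Decimal-scaling normalization: Z / 10**j, outputs in (-1, 1)."""
    Z = np.asarray(Z, dtype=float)
    return Z / 10 ** ds_exponent(Z)


# ---------------------------------------------------------------------------
# Tensor fusion
# ---------------------------------------------------------------------------


@dataclass
class FusedTensor:
    values: np.ndarray  # (size, size, 3)
    channel_roles: tuple[str, str, str] = CHANNEL_ROLES


def fuse_tensor(
    tree_map: np.ndarray, event_map: np.ndarray, depiction: np.ndarray
) -> FusedTensor:
    """Stack the three channels without mixing; shapes must agree."""
    arrays = [np.asarray(a, dtype=float) for a in (tree_map, event_map, depiction)]
    shape = arrays[0].shape
    if any(a.shape != shape or a.ndim != 2 for a in arrays):
        raise ValueError(
            f"channel shape mismatch: {[a.shape for a in arrays]}"
        )
    if not np.isin(arrays[1], (0.0, 1.0)).all():
        raise ValueError("event-indicator channel must be binary")
    return FusedTensor(values=np.stack(arrays, axis=-1))


# ---------------------------------------------------------------------------
# Handcrafted texture descriptors
# ---------------------------------------------------------------------------

GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")
LBP_BINS = 59  # uniform nri LBP with P=8, R=1


def quantize_gray(image: np.ndarray, levels: int = 8) -> np.ndarray:
    """Quantize a grayscale image to integer gray levels 0..levels-1."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * levels
    return np.clip(scaled.astype(int), 0, levels - 1).astype(np.uint8)


def glcm_features(image: np.ndarray, levels: int = 8) -> np.ndarray:
    """Haralick contrast/correlation/energy/homogeneity at 4 offsets."""
    quant = quantize_gray(image, levels)
    glcm = graycomatrix(
        quant, distances=[1], angles=list(GLCM_ANGLES), levels=levels,
        symmetric=False, normed=True,
    )
    return np.concatenate([graycoprops(glcm, p).ravel() for p in GLCM_PROPS])


def lbp_features(image: np.ndarray) -> np.ndarray:
    """59-bin normalized histogram of uniform LBP codes (P=8, R=1).

    The one-pixel border is excluded: its neighborhoods are undefined at
    radius 1, so a constant image yields a single occupied bin.
    """
    import warnings

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*floating-point images.*")
        codes = local_binary_pattern(img, P=8, R=1, method="nri_uniform")
    codes = codes[1:-1, 1:-1]
    hist, _ = np.histogram(codes, bins=np.arange(LBP_BINS + 1) - 0.5)
    return hist / max(hist.sum(), 1)


def ltrp_features(image: np.ndarray) -> np.ndarray:
    """First-order local tetra pattern histograms plus a magnitude pattern.

    Pixels are direction-coded from the signs of the horizontal and
    vertical first derivatives (four quadrant directions); each direction
    yields a uniform-LBP histogram of its binary membership map, and the
    derivative magnitude contributes one further histogram: 5 x 59 values.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    Ih = np.roll(img, -1, axis=1) - img
    Iv = np.roll(img, -1, axis=0) - img
    direction = np.select(
        [
            (Ih >= 0) & (Iv >= 0),
            (Ih < 0) & (Iv >= 0),
            (Ih < 0) & (Iv < 0),
            (Ih >= 0) & (Iv < 0),
        ],
        [1, 2, 3, 4],
    )
    blocks = []
    for g in (1, 2, 3, 4):
        blocks.append(lbp_features((direction == g).astype(float)))
    magnitude = np.sqrt(Ih**2 + Iv**2)
    blocks.append(lbp_features(magnitude))
    return np.concatenate(blocks)


def handcrafted_features(tensor: FusedTensor) -> np.ndarray:
    """Texture descriptors from the two continuous channels (tree map and
    drug depiction): GLCM + LBP + LTrP each, 740 values total."""
    blocks = []
    for channel in (0, 2):
        img = tensor.values[:, :, channel]
        blocks.extend([glcm_features(img), lbp_features(img), ltrp_features(img)])
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Row-aligned feature matrix with column provenance tags."""

    data: pd.DataFrame  # index: (cell_line, drug) pairs as strings
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_array(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def _project_block(X: np.ndarray, width: Optional[int]) -> np.ndarray:
    """Truncate or zero-pad a block to a configured width."""
    if width is None or X.shape[1] == width:
        return X
    if X.shape[1] > width:
        return X[:, :width]
    pad = np.zeros((X.shape[0], width - X.shape[1]))
    return np.hstack([X, pad])


def assemble_features(
    deep: pd.DataFrame,
    handcrafted: pd.DataFrame,
    attributes: pd.DataFrame,
    widths: Optional[tuple[int, int, int]] = None,
    handcrafted_tags: Optional[Mapping[str, str]] = None,
) -> FeatureMatrix:
    """Concatenate the deep, handcrafted and attribute blocks column-wise.

    All blocks must share the same row index of (cell line, drug) keys;
    misaligned rows raise with the offending keys listed. ``widths``
    truncates or zero-pads each block to a fixed partition (the full
    configuration uses (1024, 354, 1000) = 2,378 columns).
    """
    blocks = {"deep": deep, "handcrafted": handcrafted, "attribute": attributes}
    index = deep.index if len(deep.columns) else attributes.index
    for tag, block in blocks.items():
        if len(block.columns) and not block.index.equals(index):
            offending = sorted(set(block.index) ^ set(index))
            raise ValueError(f"row misalignment in {tag} block: {offending[:5]}")

    frames = []
    provenance: dict[str, str] = {}
    for pos, (tag, block) in enumerate(blocks.items()):
        arr = block.to_numpy(dtype=float) if len(block.columns) else np.zeros((len(index), 0))
        width = widths[pos] if widths is not None else None
        arr = _project_block(arr, width)
        names = list(block.columns)
        if width is not None:
            names = names[:width] + [
                f"{tag}_pad{k}" for k in range(max(0, width - len(names)))
            ]
        frame = pd.DataFrame(arr, index=index, columns=names)
        frames.append(frame)
        for name in names:
            if handcrafted_tags and name in handcrafted_tags:
                provenance[name] = handcrafted_tags[name]
            elif tag == "attribute" and name.startswith("drug_"):
                provenance[name] = "drug-descriptor"
            else:
                provenance[name] = tag

    data = pd.concat(frames, axis=1)
    if data.columns.duplicated().any():
        dupes = data.columns[data.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes[:5]}")
    if data.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return FeatureMatrix(data=data, provenance=provenance)


@dataclass
class FoldScaler:
    """Columnwise standardizer fitted on training rows only."""

    mean_: Optional[np.ndarray] = None
    scale_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "FoldScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def standardize_features(
    matrix: FeatureMatrix, train_mask: np.ndarray
) -> tuple[FeatureMatrix, FoldScaler]:
    """Standardize all columns using statistics from training rows only."""
    X = matrix.to_array()
    scaler = FoldScaler().fit(X[np.asarray(train_mask, dtype=bool)])
    out = pd.DataFrame(
        scaler.transform(X), index=matrix.data.index, columns=matrix.data.columns
    )
    return FeatureMatrix(data=out, provenance=dict(matrix.provenance)), scaler
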