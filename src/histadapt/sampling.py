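"""2.5D patch extraction, spatial-prior vectors and voxel sampling strategies.

A 2.5D sample is a triplet of orthogonal 2D patches (axial, sagittal,
coronal) centred on one voxel, plus the atlas probability vector at that
voxel.  Sampling strategies:

* structures — positives are all structure voxels, negatives only background
  voxels within a Chebyshev boundary margin (default 5) of some structure;
* lesions stage 1 — all lesion voxels vs. an equal random draw of non-lesion
  brain voxels;
* lesions stage 2 — all lesion voxels vs. the stage-1 false positives
  (topped up randomly when there are too few).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .volumes import LabelMap, PriorAtlas, Volume

__all__ = [
    "PatchSample",
    "SamplingPlan",
    "PatchExtractor",
    "extract_25d_patch",
    "prior_vector",
    "sample_structures",
    "sample_lesions_stage1",
    "sample_lesions_stage2",
    "split_train_val",
    "roi_from_priors",
    "assemble_arrays",
]

_CUBE = np.ones((3, 3, 3), dtype=bool)  # Chebyshev (26-connected) structuring element


@dataclass
class PatchSample:
    """Three orthogonal S×S patches + prior vector for one voxel."""

    axial: np.ndarray
    sagittal: np.ndarray
    coronal: np.ndarray
    prior: np.ndarray
    voxel: tuple[int, int, int]
    label: int | None = None


@dataclass(frozen=True)
class SamplingPlan:
    task: str = "structures"  # or "lesions"
    boundary_margin: int = 5
    balance: bool = True
    stage: int = 1
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.task not in ("structures", "lesions"):
            raise ValueError(f"unknown task {self.task!r}")


class PatchExtractor:
    """Zero-pads a volume once so repeated patch extraction is cheap slicing.

    Out-of-bounds patch entries are zero, which after per-volume intensity
    normalisation is the mean intensity.
    """

    def __init__(self, volume: Volume | np.ndarray, size: int = 32):
        data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
        if data.ndim != 3:
            raise ValueError("patch extraction requires a 3D volume")
        if size < 1:
            raise ValueError("patch size must be positive")
        self.size = int(size)
        self.shape = data.shape
        self._lo = size // 2
        pad = self.size
        self._padded = np.pad(data.astype(np.float32), pad, mode="constant")
        self._pad = pad

    def patches(self, voxel: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, y, z = (int(v) for v in voxel)
        for v, n in zip((x, y, z), self.shape):
            if not 0 <= v < n:
                raise IndexError(f"voxel {(x, y, z)} outside volume of shape {self.shape}")
        s, lo, p = self.size, self._lo, self._pad
        xs = slice(p + x - lo, p + x - lo + s)
        ys = slice(p + y - lo, p + y - lo + s)
        zs = slice(p + z - lo, p + z - lo + s)
        axial = self._padded[xs, ys, p + z]          # plane of constant z
        sagittal = self._padded[p + x, ys, zs]       # plane of constant x
        coronal = self._padded[xs, p + y, zs]        # plane of constant y
        return axial, sagittal, coronal


def extract_25d_patch(volume: Volume, voxel: Sequence[int],
                      size: int = 32) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract the (axial, sagittal, coronal) size×size patches at one voxel."""
    return PatchExtractor(volume, size).patches(voxel)


def prior_vector(atlas: PriorAtlas, voxel: Sequence[int]) -> np.ndarray:
    """The K atlas-probability channel values at a voxel."""
    x, y, z = (int(v) for v in voxel)
    for v, n in zip((x, y, z), atlas.shape):
        if not 0 <= v < n:
            raise IndexError(f"voxel {(x, y, z)} outside atlas of shape {atlas.shape}")
    return np.asarray(atlas.data[x, y, z, :], dtype=np.float32)


def sample_structures(label: LabelMap, margin: int = 5) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """All structure voxels as positives; boundary background voxels as negatives.

    Negatives are background voxels within Chebyshev distance ``margin`` of any
    structure voxel (cubic structuring element), which concentrates training on
    the hardest region — the structure borders.

    Returns ``(positives, negatives)`` with ``positives[class] -> (n, 3)`` int
    arrays and ``negatives -> (m, 3)``.
    """
    fg = label.data > 0
    if not fg.any():
        raise ValueError("label map contains no structure voxels to sample")
    positives = {
        int(c): np.argwhere(label.data == c)
        for c in np.unique(label.data) if c > 0
    }
    if margin <= 0:
        negatives = np.empty((0, 3), dtype=np.int64)
    else:
        shell = binary_dilation(fg, structure=_CUBE, iterations=margin) & ~fg
        negatives = np.argwhere(shell)
    return positives, negatives


def _check_brain(brain_mask: np.ndarray, label: LabelMap) -> np.ndarray:
    brain = np.asarray(brain_mask, dtype=bool)
    if brain.shape != label.shape:
        raise ValueError("brain mask shape must match label shape")
    return brain


def sample_lesions_stage1(label: LabelMap, brain_mask: np.ndarray,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """All lesion voxels vs. an equal seeded draw of non-lesion brain voxels."""
    brain = _check_brain(brain_mask, label)
    pos = np.argwhere(label.data > 0)
    if len(pos) == 0:
        raise ValueError("no lesion voxels to sample")
    candidates = np.argwhere(brain & (label.data == 0))
    if len(candidates) < len(pos):
        raise ValueError(
            f"need {len(pos)} non-lesion brain voxels for a balanced draw, have {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=len(pos), replace=False)
    return pos, candidates[np.sort(idx)]


def sample_lesions_stage2(label: LabelMap, stage1_prediction: LabelMap,
                          brain_mask: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """All lesion voxels vs. stage-1 false-positive voxels (false-positive reduction).

    When stage 1 produced fewer false positives than there are lesion voxels,
    the deficit is topped up with uniform random non-lesion brain voxels so
    the draw stays balanced; with more, a seeded subset of false positives of
    the positive count is used.
    """
    if stage1_prediction.shape != label.shape:
        raise ValueError("stage-1 prediction shape must match label shape")
    brain = _check_brain(brain_mask, label)
    pos = np.argwhere(label.data > 0)
    if len(pos) == 0:
        raise ValueError("no lesion voxels to sample")
    fp_mask = (stage1_prediction.data > 0) & (label.data == 0)
    fps = np.argwhere(fp_mask)
    rng = np.random.default_rng(seed)
    if len(fps) >= len(pos):
        idx = rng.choice(len(fps), size=len(pos), replace=False)
        return pos, fps[np.sort(idx)]
    extra_pool = np.argwhere(brain & (label.data == 0) & ~fp_mask)
    deficit = len(pos) - len(fps)
    if len(extra_pool) < deficit:
        raise ValueError("not enough brain voxels to balance the stage-2 draw")
    idx = rng.choice(len(extra_pool), size=deficit, replace=False)
    negatives = np.concatenate([fps, extra_pool[np.sort(idx)]], axis=0)
    return pos, negatives


def split_train_val(samples: Sequence, val_fraction: float = 0.25,
                    seed: int = 0) -> tuple[list, list]:
    """Seeded disjoint/exhaustive split; |val| = round(val_fraction * n)."""
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    n_val = int(round(val_fraction * n))
    n_val = min(max(n_val, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [samples[i] for i in range(n) if i not in val_idx]
    val = [samples[i] for i in sorted(val_idx)]
    return train, val


def roi_from_priors(atlas: PriorAtlas, dilation_radius: int = 5) -> np.ndarray:
    """Union of non-background atlas channels (p > 0), Chebyshev-dilated.

    The returned boolean mask restricts structure-mode inference to the
    central region where the structures can occur.
    """
    support = (atlas.data[..., 1:] > 0).any(axis=-1)
    if dilation_radius > 0 and support.any():
        support = binary_dilation(support, structure=_CUBE, iterations=int(dilation_radius))
    return support


def assemble_arrays(volume: Volume, atlas: PriorAtlas, voxels: np.ndarray,
                    labels: np.ndarray | None, size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Stack patch triplets and prior vectors for many voxels.

    Returns ``(patches (n, 3, size, size) float32, priors (n, K) float32,
    labels (n,) int64 or None)`` with patch channel order (axial, sagittal,
    coronal).
    """
    voxels = np.asarray(voxels, dtype=np.int64)
    extractor = PatchExtractor(volume, size)
    n = len(voxels)
    patches = np.empty((n, 3, size, size), dtype=np.float32)
    for i, v in enumerate(voxels):
        a, s, c = extractor.patches(v)
        patches[i, 0], patches[i, 1], patches[i, 2] = a, s, c
    priors = atlas.data[voxels[:, 0], voxels[:, 1], voxels[:, 2], :].astype(np.float32)
    lab = None if labels is None else np.asarray(labels, dtype=np.int64)
    return patches, priors, lab
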