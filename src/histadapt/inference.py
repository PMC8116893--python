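"""Whole-volume segmentation and task-specific post-processing.

Structure mode classifies only voxels inside a region of interest derived
from the dilated atlas support and keeps a single (largest) connected
component per class.  Lesion mode classifies every brain voxel, thresholds
the lesion probability, and removes candidates that are outside white matter
or smaller than a minimum physical volume (default 3 mm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import Network
from .sampling import assemble_arrays, roi_from_priors
from .volumes import LabelMap, PriorAtlas, Volume

__all__ = ["SegmentationResult", "segment_volume", "keep_largest_component",
           "filter_lesion_candidates"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """Class probabilities, the discrete label map, and the processed region."""

    probabilities: np.ndarray          # (nx, ny, nz, n_classes), zero outside mask
    labels: LabelMap
    processed_mask: np.ndarray         # boolean, ROI (structures) or brain (lesions)
    manifest: dict = field(default_factory=dict)


def segment_volume(network: Network, volume: Volume, priors: PriorAtlas,
                   mode: str = "structures", threshold: float = 0.5,
                   roi_dilation: int = 5, batch_size: int = 2048,
                   brain_mask: np.ndarray | None = None,
                   postprocess: bool = True) -> SegmentationResult:
    """Classify every voxel of the processed region with the patch network.

    ``volume`` must already be intensity-normalised.  In structures mode the
    processed region is the dilated atlas support and labels are the argmax
    class; in lesions mode it is the brain mask (non-zero voxels by default)
    and the label is 1 where the lesion probability reaches ``threshold``.
    Post-processing (largest component per class / lesion candidate filtering)
    can be disabled for intermediate cascade predictions.
    """
    if volume.shape != priors.shape:
        raise ValueError("volume and prior atlas shapes differ")
    if mode not in ("structures", "lesions"):
        raise ValueError(f"unknown mode {mode!r}")
    n_classes = network.spec.out_classes
    if mode == "structures" and priors.n_classes != n_classes:
        raise ValueError("structure atlas channel count must match network classes")

    if mode == "structures":
        mask = roi_from_priors(priors, dilation_radius=roi_dilation)
    else:
        mask = (volume.data != 0) if brain_mask is None else np.asarray(brain_mask, bool)

    probs = np.zeros(volume.shape + (n_classes,), dtype=np.float32)
    labels = np.zeros(volume.shape, dtype=np.int32)
    voxels = np.argwhere(mask)
    manifest: dict = {"mode": mode, "n_processed_voxels": int(len(voxels))}
    if len(voxels):
        patch_size = network.spec.patch_size
        p = np.empty((len(voxels), n_classes), dtype=np.float64)
        for i in range(0, len(voxels), batch_size):
            chunk = voxels[i:i + batch_size]
            patches, pri, _ = assemble_arrays(volume, priors, chunk, None, patch_size)
            p[i:i + len(chunk)] = network.predict_proba(patches, pri, batch_size=batch_size)
        probs[tuple(voxels.T)] = p.astype(np.float32)
        if mode == "structures":
            labels[tuple(voxels.T)] = p.argmax(axis=1)
        else:
            labels[tuple(voxels.T)] = (p[:, 1] >= threshold).astype(np.int32)
            manifest["threshold"] = float(threshold)

    label_map = LabelMap(labels, class_count=n_classes, spacing=volume.spacing,
                         affine=volume.affine)
    if postprocess and len(voxels):
        if mode == "structures":
            before = int(label_map.data.max() >= 0)
            for c in range(1, n_classes):
                label_map = keep_largest_component(label_map, c)
            manifest["largest_component_per_class"] = True
        else:
            lesion_mask = label_map.data == 1
            n_before = ndimage.label(lesion_mask, structure=_CONN26)[1]
            filtered = filter_lesion_candidates(
                lesion_mask, priors.data[..., 0], volume.spacing,
                min_volume_mm3=3.0, wm_threshold=0.5)
            n_after = ndimage.label(filtered, structure=_CONN26)[1]
            label_map = LabelMap(filtered.astype(np.int32), class_count=n_classes,
                                 spacing=volume.spacing, affine=volume.affine)
            manifest["candidates_before"] = int(n_before)
            manifest["candidates_after"] = int(n_after)
    return SegmentationResult(probabilities=probs, labels=label_map,
                              processed_mask=mask, manifest=manifest)


def keep_largest_component(labels: LabelMap, class_index: int) -> LabelMap:
    """Keep only the largest 26-connected component of one class.

    Ties are broken deterministically in favour of the component containing
    the lexicographically smallest voxel.  Other classes are untouched; an
    absent class is a no-op.
    """
    mask = labels.data == class_index
    if not mask.any():
        return labels
    comp, n = ndimage.label(mask, structure=_CONN26)
    if n <= 1:
        return labels
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie: pick the component whose smallest member voxel comes first
        firsts = [tuple(np.argwhere(comp == b)[0]) for b in best]
        best = [best[int(np.lexsort(np.array(firsts).T[::-1])[0])]]
    keep = comp == best[0]
    out = labels.data.copy()
    out[mask & ~keep] = 0
    return LabelMap(out, class_count=labels.class_count,
                    spacing=labels.spacing, affine=labels.affine)


def filter_lesion_candidates(mask: np.ndarray, wm_prior: np.ndarray,
                             spacing, min_volume_mm3: float = 3.0,
                             wm_threshold: float = 0.5) -> np.ndarray:
    """Remove lesion candidates outside white matter or below a volume floor.

    Candidates are 26-connected components.  A candidate is removed when its
    physical volume (voxel count × voxel volume) is strictly less than
    ``min_volume_mm3``, or when fewer than half of its voxels have WM prior
    probability ≥ ``wm_threshold``.
    """
    mask = np.asarray(mask, dtype=bool)
    wm_prior = np.asarray(wm_prior)
    if mask.shape != wm_prior.shape:
        raise ValueError("mask and WM prior shapes differ")
    if not mask.any():
        return mask.copy()
    voxel_vol = float(np.prod(spacing))
    comp, n = ndimage.label(mask, structure=_CONN26)
    out = np.zeros_like(mask)
    in_wm = wm_prior >= wm_threshold
    for c in range(1, n + 1):
        cm = comp == c
        size = int(cm.sum())
        if size * voxel_vol < min_volume_mm3:
            continue
        if in_wm[cm].mean() < 0.5:
            continue
        out |= cm
    return out
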