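"""ROI summarisation: mask erosion, region statistics and brain parenchymal fraction.

Normal-appearing white matter (NAWM) is the supplied white-matter mask
minus the lesion mask, eroded by one voxel (26-connectivity box kernel)
to limit partial-volume contamination at tissue boundaries.  Region
statistics exclude NaN-flagged voxels; the brain parenchymal fraction
(BPF) is brain volume, including lesions, over intracranial volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VolumeMap

__all__ = [
    "RegionSummary",
    "erode_mask",
    "nawm_mask",
    "summarise_region",
    "compute_bpf",
]


@dataclass
class RegionSummary:
    """Summary statistics for one map within one region."""

    mean: float
    median: float
    sd: float
    n_voxels: int


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Morphological erosion with a 3x3x3 box structuring element.

    Warns (and returns an all-False mask) if the result is empty.
    """
    mask = np.asarray(mask).astype(bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    structure = np.ones((3, 3, 3), dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=structure, iterations=iterations)
    if not eroded.any():
        warnings.warn("erosion produced an empty mask", stacklevel=2)
    return eroded


def nawm_mask(wm: np.ndarray, wml: np.ndarray | None, iterations: int = 1) -> np.ndarray:
    """NAWM = (WM minus WML) eroded by ``iterations`` voxels."""
    wm = np.asarray(wm).astype(bool)
    nawm = wm if wml is None else (wm & ~np.asarray(wml).astype(bool))
    return erode_mask(nawm, iterations=iterations)


def summarise_region(
    vol: VolumeMap,
    mask: np.ndarray,
    exclusion: np.ndarray | None = None,
) -> RegionSummary:
    """Mean/median/SD/count of finite voxels within mask minus exclusion."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape:
        raise ValueError("mask grid does not match volume grid")
    if exclusion is not None:
        exclusion = np.asarray(exclusion).astype(bool)
        if exclusion.shape != vol.shape:
            raise ValueError("exclusion grid does not match volume grid")
        mask = mask & ~exclusion
    values = vol.data[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty effective mask (no valid voxels)")
    return RegionSummary(
        mean=float(values.mean()),
        median=float(np.median(values)),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n_voxels=int(values.size),
    )


def compute_bpf(brain: np.ndarray, icv: np.ndarray, voxel_volume: float = 1.0) -> float:
    """Brain parenchymal fraction: brain volume (incl. lesions) / ICV volume."""
    brain = np.asarray(brain).astype(bool)
    icv = np.asarray(icv).astype(bool)
    n_icv = int(icv.sum())
    if n_icv == 0:
        raise ValueError("ICV mask is empty")
    if np.any(brain & ~icv):
        raise ValueError("brain mask extends outside the ICV mask")
    return float(brain.sum() * voxel_volume) / float(n_icv * voxel_volume)
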