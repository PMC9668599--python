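"""Minimal 3D volume and mask containers backed by nibabel for I/O.

A :class:`VolumeMap` couples a floating-point data array with its voxel
geometry (affine).  Invalid voxels (failed inversions, divisions by ~0)
are flagged as NaN; downstream ROI statistics exclude them rather than
treating them as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeMap", "MaskSet"]


@dataclass
class VolumeMap:
    """One 3D scalar map with voxel geometry.

    ``data`` is float; NaN marks voxels flagged invalid.  ``affine`` maps
    voxel indices to world (mm) coordinates, default 1 mm isotropic.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VolumeMap") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def valid_mask(self) -> np.ndarray:
        """Boolean array of voxels carrying a finite value."""
        return np.isfinite(self.data)

    def with_data(self, data: np.ndarray) -> "VolumeMap":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    # ---- NIfTI I/O -------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeMap":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.get_fdata(), dtype=np.float64), affine=img.affine)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        arr = arr.astype(bool)
    return arr


@dataclass
class MaskSet:
    """Binary ROI volumes for one subject/timepoint.

    ``wm`` is the full white-matter mask; normal-appearing white matter is
    derived downstream as wm minus wml followed by one-voxel erosion.
    ``exclude`` (optional) removes regions, e.g. the cerebellum, from
    diffusion-based and g-ratio statistics.
    """

    brain: np.ndarray
    icv: np.ndarray
    wm: np.ndarray
    wml: np.ndarray | None = None
    exclude: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.brain = _as_bool(self.brain)
        self.icv = _as_bool(self.icv)
        self.wm = _as_bool(self.wm)
        if self.wml is not None:
            self.wml = _as_bool(self.wml)
        if self.exclude is not None:
            self.exclude = _as_bool(self.exclude)
        shapes = {m.shape for m in self._all_masks()}
        if len(shapes) != 1:
            raise ValueError(f"mask grids differ: {shapes}")

    def _all_masks(self):
        for m in (self.brain, self.icv, self.wm, self.wml, self.exclude):
            if m is not None:
                yield m

    def save(self, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name in ("brain", "icv", "wm", "wml", "exclude"):
            mask = getattr(self, name)
            if mask is None:
                continue
            path = outdir / f"{prefix}{name}.nii.gz"
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), self.affine), str(path))
            written[name] = path
        return written

    @classmethod
    def load(cls, outdir: str | Path, prefix: str = "") -> "MaskSet":
        outdir = Path(outdir)
        kwargs = {}
        for name in ("brain", "icv", "wm", "wml", "exclude"):
            path = outdir / f"{prefix}{name}.nii.gz"
            if path.exists():
                img = nib.load(str(path))
                kwargs[name] = np.asarray(img.get_fdata()) > 0.5
                kwargs["affine"] = img.affine
        missing = {"brain", "icv", "wm"} - set(kwargs)
        if missing:
            raise FileNotFoundError(f"required masks not found in {outdir}: {sorted(missing)}")
        return cls(**kwargs)
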