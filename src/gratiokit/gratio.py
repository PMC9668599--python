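"""Aggregate MRI g-ratio mapping from MTsat and NODDI volume fractions.

The voxelwise aggregate g-ratio (inner axon diameter over outer
myelinated-fibre diameter) is

    g = sqrt( AVF / (AVF + MVF) )

with the myelin volume fraction taken as linearly scaled MTsat,
MVF = k * MTsat[%], and the axonal volume fraction assembled from the
NODDI restricted and free-water fractions,

    AVF = (1 - MVF) (1 - ISOVF) ICVF.

The scaling constant ``k`` is not known a priori; it is calibrated so
that the pooled healthy-control white-matter mean g equals a target
value (default 0.581).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .volume import VolumeMap

__all__ = [
    "GratioMaps",
    "compute_mvf",
    "compute_avf",
    "compute_gratio",
    "calibrate_k",
    "fit_gratio_maps",
]

logger = logging.getLogger(__name__)

#: Default pooled control white-matter mean g used for calibration.
DEFAULT_G_TARGET = 0.581


@dataclass
class GratioMaps:
    """MVF/AVF/g volumes plus the MVF scaling constant used."""

    mvf: VolumeMap
    avf: VolumeMap
    g: VolumeMap
    k: float


def compute_mvf(mtsat: VolumeMap, k: float) -> VolumeMap:
    """Myelin volume fraction as linearly scaled MTsat (percent units).

    Values are clipped to [0, 1]; clip events are logged, NaN propagates.
    """
    if not (k > 0):
        raise ValueError(f"k must be positive, got {k!r}")
    raw = k * mtsat.data
    clipped = np.clip(raw, 0.0, 1.0)
    n_clip = int(np.sum((raw < 0) | (raw > 1)))
    if n_clip:
        logger.info("compute_mvf: clipped %d voxels into [0, 1]", n_clip)
    return mtsat.with_data(clipped)


def _check_fraction(name: str, arr: np.ndarray) -> None:
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


def compute_avf(mvf: VolumeMap, isovf: VolumeMap, icvf: VolumeMap) -> VolumeMap:
    """Axonal volume fraction AVF = (1 - MVF)(1 - ISOVF) ICVF."""
    for name, vol in (("mvf", mvf), ("isovf", isovf), ("icvf", icvf)):
        _check_fraction(name, vol.data)
    return mvf.with_data((1.0 - mvf.data) * (1.0 - isovf.data) * icvf.data)


def compute_gratio(mvf: VolumeMap, avf: VolumeMap) -> VolumeMap:
    """g = sqrt(AVF / (AVF + MVF)); voxels with AVF = 0 are undefined (NaN)."""
    _check_fraction("mvf", mvf.data)
    _check_fraction("avf", avf.data)
    m, a = mvf.data, avf.data
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.sqrt(a / (a + m))
    g = np.where(a > 0, g, np.nan)
    return mvf.with_data(g)


def _pooled_mean_g(
    mtsat_maps: Sequence[VolumeMap],
    icvf_maps: Sequence[VolumeMap],
    isovf_maps: Sequence[VolumeMap],
    wm_masks: Sequence[np.ndarray],
    k: float,
) -> float:
    values = []
    for mtsat, icvf, isovf, wm in zip(mtsat_maps, icvf_maps, isovf_maps, wm_masks):
        mvf = compute_mvf(mtsat, k)
        avf = compute_avf(mvf, isovf, icvf)
        g = compute_gratio(mvf, avf).data
        # fully myelinated voxels (AVF -> 0 with MVF > 0) take the g -> 0
        # limit here so the calibration objective stays monotone in k
        g = np.where((avf.data == 0) & (mvf.data > 0), 0.0, g)
        g = g[np.asarray(wm, dtype=bool)]
        values.append(g[np.isfinite(g)])
    pooled = np.concatenate(values)
    if pooled.size == 0:
        raise ValueError("no valid white-matter voxels for calibration")
    return float(pooled.mean())


def calibrate_k(
    mtsat_maps: Sequence[VolumeMap],
    icvf_maps: Sequence[VolumeMap],
    isovf_maps: Sequence[VolumeMap],
    wm_masks: Sequence[np.ndarray],
    g_target: float = DEFAULT_G_TARGET,
    bracket: tuple[float, float] = (1e-6, 0.9),
    tol: float = 1e-6,
) -> float:
    """Find k such that the pooled control WM mean g equals ``g_target``.

    The pooled mean g is strictly decreasing in k (more myelin, lower g),
    so a bracketed 1-D root find is exact and deterministic.

    Raises
    ------
    ValueError
        If ``g_target`` is not attainable within ``bracket``.
    """
    if not (0.0 < g_target < 1.0):
        raise ValueError("g_target must lie in (0, 1)")
    if len(mtsat_maps) == 0:
        raise ValueError("need at least one control subject")

    def objective(k: float) -> float:
        return _pooled_mean_g(mtsat_maps, icvf_maps, isovf_maps, wm_masks, k) - g_target

    lo, hi = bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"g_target={g_target} not attainable: mean g spans "
            f"[{f_hi + g_target:.4f}, {f_lo + g_target:.4f}] over k in {bracket}"
        )
    k = float(brentq(objective, lo, hi, xtol=1e-12, rtol=8.9e-16))
    residual = objective(k)
    if abs(residual) > tol:
        raise RuntimeError(f"calibration residual {residual:.2e} exceeds tol {tol:.2e}")
    return k


def fit_gratio_maps(
    mtsat: VolumeMap, icvf: VolumeMap, isovf: VolumeMap, k: float
) -> GratioMaps:
    """MVF -> AVF -> g chain for one subject/timepoint."""
    mvf = compute_mvf(mtsat, k)
    avf = compute_avf(mvf, isovf, icvf)
    g = compute_gratio(mvf, avf)
    return GratioMaps(mvf=mvf, avf=avf, g=g, k=k)
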