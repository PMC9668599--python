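"""MTR and MTsat parametric mapping from dual-flip-angle FLASH volumes.

The magnetisation transfer ratio is the classical normalised difference

    MTR = 100 (S_off - S_on) / S_off   [percent]

and is confounded by T1 and B1.  The MT saturation fraction ``delta``
(reported x100 as MTsat percent) removes the flip-angle and T1 dependence
analytically: the MT_off / MT_T1w pair gives apparent amplitude and R1
via the dual-flip-angle (variable flip angle) estimators, and ``delta``
follows from the MT_on signal:

    R1_app = (1/2) (S_T1w a2 / TR2 - S_off a1 / TR1)
                 / (S_off / a1 - S_T1w / a2)
    A_app  = S_off S_T1w (TR1 a2/a1 - TR2 a1/a2)
                 / (S_T1w TR1 a2 - S_off TR2 a1)
    delta  = (A_app a1 / S_on - 1) R1_app TR1 - a1^2 / 2

All estimators are exact inverses of the rational FLASH forward model and
small-angle approximations of the exact spoiled gradient-echo signal.
Voxels where an inversion is undefined (non-positive signals, singular
denominators) are flagged NaN, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams
from .volume import VolumeMap

__all__ = [
    "MtMaps",
    "sum_echoes",
    "compute_mtr",
    "estimate_t1_amplitude",
    "compute_mtsat",
    "fit_mt_maps",
]


@dataclass
class MtMaps:
    """Parametric maps from one MT acquisition.

    mtr and mtsat are in percent; a_app in signal units; r1_app in 1/s.
    NaN voxels failed a validity check.
    """

    mtr: VolumeMap
    mtsat: VolumeMap
    a_app: VolumeMap
    r1_app: VolumeMap


def sum_echoes(echoes: list[VolumeMap]) -> VolumeMap:
    """Voxelwise sum of echo volumes (raises SNR of the combined image)."""
    if len(echoes) == 0:
        raise ValueError("need at least one echo")
    first = echoes[0]
    for e in echoes[1:]:
        if not first.same_grid(e):
            raise ValueError("echo volumes are not on the same grid")
    total = np.sum([e.data for e in echoes], axis=0)
    return first.with_data(total)


def compute_mtr(s_on: VolumeMap, s_off: VolumeMap, eps: float = 1e-12) -> VolumeMap:
    """MTR in percent; voxels with S_off <= eps are flagged NaN."""
    if not s_on.same_grid(s_off):
        raise ValueError("S_on and S_off are not on the same grid")
    off = s_off.data
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = 100.0 * (off - s_on.data) / off
    mtr = np.where(off > eps, mtr, np.nan)
    return s_off.with_data(mtr)


def estimate_t1_amplitude(
    s_off: VolumeMap, s_t1w: VolumeMap, acq: AcquisitionParams
) -> tuple[VolumeMap, VolumeMap]:
    """Dual-flip-angle apparent amplitude and R1 estimates.

    Returns ``(a_app, r1_app)``.  Voxels with non-positive signals or a
    non-positive estimator denominator (degenerate flip-angle pair) are NaN.
    """
    if not s_off.same_grid(s_t1w):
        raise ValueError("S_off and S_T1w are not on the same grid")
    a1, a2, tr1, tr2 = acq.alpha1, acq.alpha2, acq.tr1, acq.tr2

    off, t1w = s_off.data, s_t1w.data
    with np.errstate(divide="ignore", invalid="ignore"):
        den_r1 = off / a1 - t1w / a2
        r1 = 0.5 * (t1w * a2 / tr2 - off * a1 / tr1) / den_r1
        den_a = t1w * tr1 * a2 - off * tr2 * a1
        a_app = off * t1w * (tr1 * a2 / a1 - tr2 * a1 / a2) / den_a

    bad = (off <= 0) | (t1w <= 0) | (den_r1 <= 0) | (den_a <= 0)
    r1 = np.where(bad, np.nan, r1)
    a_app = np.where(bad, np.nan, a_app)
    return s_off.with_data(a_app), s_off.with_data(r1)


def compute_mtsat(
    s_on: VolumeMap,
    a_app: VolumeMap,
    r1_app: VolumeMap,
    acq: AcquisitionParams,
) -> VolumeMap:
    """MTsat in percent (100 x per-excitation saturation fraction).

    Negative values are permitted (noise floor); voxels with invalid
    A_app/R1_app or non-positive S_on are NaN.
    """
    for other in (a_app, r1_app):
        if not s_on.same_grid(other):
            raise ValueError("inputs are not on the same grid")
    a1, tr1 = acq.alpha1, acq.tr1
    on = s_on.data
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a_app.data * a1 / on - 1.0) * r1_app.data * tr1 - a1**2 / 2.0
    delta = np.where(on > 0, delta, np.nan)
    return s_on.with_data(100.0 * delta)


def fit_mt_maps(
    s_on: VolumeMap,
    s_off: VolumeMap,
    s_t1w: VolumeMap,
    acq: AcquisitionParams,
) -> MtMaps:
    """Full MT fitting chain on echo-summed volumes."""
    a_app, r1_app = estimate_t1_amplitude(s_off, s_t1w, acq)
    return MtMaps(
        mtr=compute_mtr(s_on, s_off),
        mtsat=compute_mtsat(s_on, a_app, r1_app, acq),
        a_app=a_app,
        r1_app=r1_app,
    )
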