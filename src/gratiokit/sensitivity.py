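"""Post-hoc sensitivity of the g-ratio to its MRI inputs.

The aggregate g-ratio responds in competing directions to its inputs:
lower MTsat (less myelin) raises g, higher ICVF raises g, and higher
ISOVF lowers g.  ``sweep_g`` substitutes biologically realistic values
of one input (others fixed) through the MVF -> AVF -> g chain and
records the resulting g values and finite-difference signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gratio import compute_avf, compute_gratio, compute_mvf
from .volume import VolumeMap

__all__ = ["SimGrid", "sweep_g", "DEFAULT_RANGES", "DEFAULT_FIXED"]

AXES = ("mtsat", "icvf", "isovf")

#: Biologically realistic sweep ranges, from the cohort's observed
#: white-matter ranges: MTsat in percent, NODDI fractions dimensionless.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mtsat": (1.7, 4.3),
    "icvf": (0.27, 0.65),
    "isovf": (0.04, 0.19),
}

#: Default fixed values (healthy NAWM-like operating point).
DEFAULT_FIXED: dict[str, float] = {"mtsat": 3.8, "icvf": 0.58, "isovf": 0.075}


@dataclass
class SimGrid:
    """One axis sweep through the g-ratio chain."""

    axis: str
    values: np.ndarray
    fixed: dict[str, float]
    k: float
    g: np.ndarray
    diff_signs: np.ndarray  # sign of successive finite differences of g


def _evaluate_g(mtsat: np.ndarray, icvf: np.ndarray, isovf: np.ndarray, k: float) -> np.ndarray:
    shape = np.broadcast(mtsat, icvf, isovf).shape
    as_vol = lambda x: VolumeMap(np.broadcast_to(np.asarray(x, float), shape).reshape(-1, 1, 1))
    mvf = compute_mvf(as_vol(mtsat), k)
    avf = compute_avf(mvf, as_vol(isovf), as_vol(icvf))
    return compute_gratio(mvf, avf).data.ravel()


def sweep_g(
    axis: str,
    sweep_range: tuple[float, float],
    fixed: dict[str, float],
    k: float,
    n: int = 50,
) -> SimGrid:
    """Evaluate g along one input axis, the other two held fixed.

    ``fixed`` must supply the two non-swept inputs.  Combinations that
    drive AVF to zero yield NaN g values and raise, since the sweep is
    then outside the model's domain.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    lo, hi = sweep_range
    if not (lo < hi):
        raise ValueError("sweep range must be increasing")
    if axis != "mtsat" and not (0.0 <= lo and hi <= 1.0):
        raise ValueError(f"{axis} range must lie within [0, 1]")
    if axis == "mtsat" and lo <= 0:
        raise ValueError("mtsat range must be positive")
    missing = set(AXES) - {axis} - set(fixed)
    if missing:
        raise ValueError(f"fixed values missing for {sorted(missing)}")

    values = np.linspace(lo, hi, n)
    inputs = {name: np.full(n, fixed[name]) for name in AXES if name != axis}
    inputs[axis] = values
    g = _evaluate_g(inputs["mtsat"], inputs["icvf"], inputs["isovf"], k)
    if not np.all(np.isfinite(g)):
        raise ValueError("sweep drives AVF to 0 (undefined g) for some values")
    return SimGrid(
        axis=axis,
        values=values,
        fixed={name: fixed[name] for name in AXES if name != axis},
        k=k,
        g=g,
        diff_signs=np.sign(np.diff(g)),
    )
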