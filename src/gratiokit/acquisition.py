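"""Acquisition parameters of the magnetisation-transfer FLASH protocol.

The MT protocol consists of three spoiled gradient-echo (FLASH) volumes:
a proton-density-weighted pair acquired with and without an off-resonance
MT saturation pulse (``MT_on`` / ``MT_off``, low flip angle, long TR) and
a T1-weighted volume (higher flip angle, short TR).  Together they allow
voxelwise estimation of the apparent amplitude ``A_app``, apparent
longitudinal relaxation rate ``R1_app`` and the per-excitation MT
saturation fraction ``delta`` (reported x100 as MTsat percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionParams:
    """Flip angles and repetition times of the dual-flip-angle FLASH protocol.

    Parameters
    ----------
    alpha1 : float
        Excitation flip angle of the MT_off / MT_on volumes, in radians.
    alpha2 : float
        Excitation flip angle of the T1-weighted volume, in radians.
    tr1, tr2 : float
        Repetition times (seconds) of the PD-weighted and T1-weighted
        volumes respectively.
    echo_times : tuple of float
        Echo times (seconds) of the multi-echo readout; metadata only —
        echoes are summed before map fitting.
    """

    alpha1: float
    alpha2: float
    tr1: float
    tr2: float
    echo_times: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < self.alpha2 < math.pi / 2):
            raise ValueError(
                "flip angles must satisfy 0 < alpha1 < alpha2 < pi/2 (radians); "
                f"got alpha1={self.alpha1!r}, alpha2={self.alpha2!r}"
            )
        if self.tr1 <= 0 or self.tr2 <= 0:
            raise ValueError("repetition times must be positive")
        if any(te <= 0 for te in self.echo_times):
            raise ValueError("echo times must be positive")

    @classmethod
    def from_degrees_ms(
        cls,
        flip1_deg: float,
        flip2_deg: float,
        tr1_ms: float,
        tr2_ms: float,
        echo_times_ms: tuple[float, ...] = (),
    ) -> "AcquisitionParams":
        """Build from flip angles in degrees and times in milliseconds."""
        return cls(
            alpha1=math.radians(flip1_deg),
            alpha2=math.radians(flip2_deg),
            tr1=tr1_ms / 1000.0,
            tr2=tr2_ms / 1000.0,
            echo_times=tuple(te / 1000.0 for te in echo_times_ms),
        )


#: The 3 T protocol emulated throughout this package: 5 deg / 18 deg flips,
#: TR 30 / 15 ms, three echoes at 1.54 / 4.55 / 8.49 ms.
DEFAULT_PROTOCOL = AcquisitionParams.from_degrees_ms(
    flip1_deg=5.0,
    flip2_deg=18.0,
    tr1_ms=30.0,
    tr2_ms=15.0,
    echo_times_ms=(1.54, 4.55, 8.49),
)
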