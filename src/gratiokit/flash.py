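"""Forward simulation of spoiled gradient-echo (FLASH) steady-state signals.

Two forward models are provided:

``exact``
    The Ernst steady-state of an ideally spoiled gradient echo,
    ``S = A sin(a) (1 - E1) / (1 - cos(a) E1)`` with ``E1 = exp(-TR R1)``.
    When the off-resonance MT pulse is on, each excitation additionally
    saturates the longitudinal magnetisation by the fraction ``delta``,
    which enters the steady state alongside the cosine loss term.

``rational``
    The small-angle / short-TR rational approximation
    ``S = A a TR R1 / (a^2/2 + delta + TR R1)`` — the algebraic form that
    the dual-flip-angle MTsat estimator inverts exactly.  Simulating with
    this model therefore separates estimator correctness (exact recovery)
    from model approximation error (characterised with ``exact``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_flash_signal"]

_MODELS = ("exact", "rational")


def simulate_flash_signal(
    a,
    r1,
    delta,
    flip: float,
    tr: float,
    model: str = "rational",
    mt_on: bool = False,
):
    """Steady-state FLASH signal for tissue ``(a, r1, delta)``.

    Parameters
    ----------
    a : array_like
        Signal amplitude (arbitrary units, > 0); proportional to PD and
        receive sensitivity.
    r1 : array_like
        Apparent longitudinal relaxation rate, 1/s (> 0).
    delta : array_like
        Per-excitation MT saturation fraction (>= 0, dimensionless).
        Ignored unless ``mt_on``.
    flip : float
        Excitation flip angle, radians, in (0, pi/2).
    tr : float
        Repetition time, seconds (> 0).
    model : {"rational", "exact"}
    mt_on : bool
        Whether the off-resonance saturation pulse is applied.

    Returns
    -------
    ndarray or float
        Signal in the units of ``a``.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    if not np.isfinite(flip) or not (0.0 < flip < np.pi / 2):
        raise ValueError(f"flip must lie in (0, pi/2) radians, got {flip!r}")
    if not np.isfinite(tr) or tr <= 0:
        raise ValueError(f"tr must be positive, got {tr!r}")

    a = np.asarray(a, dtype=np.float64)
    r1 = np.asarray(r1, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    for name, arr in (("a", a), ("r1", r1), ("delta", delta)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
    if np.any(a <= 0):
        raise ValueError("a must be positive")
    if np.any(r1 <= 0):
        raise ValueError("r1 must be positive")
    if np.any(delta < 0):
        raise ValueError("delta must be non-negative")

    d = delta if mt_on else np.zeros_like(delta)

    if model == "rational":
        signal = a * flip * tr * r1 / (flip**2 / 2.0 + d + tr * r1)
    else:
        # Ideally spoiled SPGR steady state; the MT pulse removes the
        # fraction ``delta`` of longitudinal magnetisation each TR, so the
        # effective per-TR recovery factor becomes cos(a)(1-delta)E1.
        e1 = np.exp(-tr * r1)
        signal = a * np.sin(flip) * (1.0 - e1) / (1.0 - np.cos(flip) * (1.0 - d) * e1)

    if signal.ndim == 0:
        return float(signal)
    return signal
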