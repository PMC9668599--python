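"""Test-retest agreement: Bland-Altman limits and exact sign tests.

The Bland-Altman limits of agreement, mean difference +/- 1.96 SD of the
paired differences, give the range within which ~95% of repeat
measurements in stable subjects are expected to fall; they serve as
reference levels against which pathological longitudinal change is
judged.  The sign test asks whether repeat differences are symmetric
about zero without any distributional assumption; at the small sample
sizes typical of test-retest arms (n ~ 10) the exact binomial version is
required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "bland_altman", "sign_test"]


@dataclass
class AgreementResult:
    """Bland-Altman agreement summary for one metric/region."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_half_width: float
    loa_low: float
    loa_high: float
    sign_test_p: float
    #: per-subject (average, difference) pairs, for plotting
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def sign_test(values_t1, values_t2) -> float:
    """Exact two-sided sign test for paired data.

    Zero differences are dropped (logged); with m non-tied pairs and k
    positive differences, p = min(1, 2 min(P(X<=k), P(X>=k))) for
    X ~ Binomial(m, 1/2).  All-tied input returns p = 1 with a warning.
    """
    d = np.asarray(values_t2, dtype=float) - np.asarray(values_t1, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one pair")
    nonzero = d[d != 0]
    m = nonzero.size
    if m == 0:
        warnings.warn("all paired differences are zero; sign test p = 1", stacklevel=2)
        return 1.0
    if m < d.size:
        warnings.warn(f"dropped {d.size - m} zero differences", stacklevel=2)
    k = int(np.sum(nonzero > 0))
    p_low = stats.binom.cdf(k, m, 0.5)
    p_high = stats.binom.sf(k - 1, m, 0.5)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def bland_altman(values_t1, values_t2) -> AgreementResult:
    """Bland-Altman agreement statistics for paired measurements.

    Differences are t2 - t1; sd uses the n-1 denominator; limits are
    mean +/- 1.96 sd (the conventional 95% multiplier).
    """
    v1 = np.asarray(values_t1, dtype=float)
    v2 = np.asarray(values_t2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("paired value arrays must have equal shape")
    if v1.size < 2:
        raise ValueError("need at least two pairs")
    d = v2 - v1
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    half = 1.96 * sd_diff
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sign_test(v1, v2)
    return AgreementResult(
        n=int(v1.size),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_half_width=half,
        loa_low=mean_diff - half,
        loa_high=mean_diff + half,
        sign_test_p=p,
        means=(v1 + v2) / 2.0,
        diffs=d,
    )
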