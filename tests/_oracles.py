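"""Independent oracles used by the test suite.

The normal quantile here is coded from scratch (Acklam's rational
approximation polished with one Halley step on ``math.erfc``) so that
signal-detection identities can be checked against a routine that shares
no code with the implementation under test.  Accuracy is ~1e-15.
"""

from __future__ import annotations

import math

_A = [
    -3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
    1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00,
]
_B = [
    -5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
    6.680131188771972e01, -1.328068155288572e01,
]
_C = [
    -7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
    -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00,
]
_D = [
    7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
    3.754408661907416e00,
]


def norm_ppf(p: float) -> float:
    """Standard normal quantile, independent of scipy."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    p_low, p_high = 0.02425, 1 - 0.02425
    if p < p_low:
        q = math.sqrt(-2 * math.log(p))
        x = (((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5]) / (
            (((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1
        )
    elif p <= p_high:
        q = p - 0.5
        r = q * q
        x = (((((_A[0] * r + _A[1]) * r + _A[2]) * r + _A[3]) * r + _A[4]) * r + _A[5]) * q / (
            ((((_B[0] * r + _B[1]) * r + _B[2]) * r + _B[3]) * r + _B[4]) * r + 1
        )
    else:
        q = math.sqrt(-2 * math.log(1 - p))
        x = -(((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5]) / (
            (((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1
        )
    # one Halley refinement against the exact CDF
    e = 0.5 * math.erfc(-x / math.sqrt(2)) - p
    u = e * math.sqrt(2 * math.pi) * math.exp(x * x / 2)
    return x - u / (1 + x * u / 2)


def norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2))


def sdt_from_counts(hits: int, n_signal: int, fas: int, n_noise: int):
    """Brute-force d'/c from counts with the conditional loglinear rule."""
    H = hits / n_signal
    F = fas / n_noise
    if H in (0.0, 1.0) or F in (0.0, 1.0):
        H = (hits + 0.5) / (n_signal + 1)
        F = (fas + 0.5) / (n_noise + 1)
    zh, zf = norm_ppf(H), norm_ppf(F)
    return zh - zf, -(zh + zf) / 2.0
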