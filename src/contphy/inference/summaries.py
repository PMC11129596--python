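"""Posterior trace summaries: HPD intervals and effective sample sizes."""

from __future__ import annotations

import math

import numpy as np

from ..errors import ValidationError

__all__ = ["hpd_interval", "ess"]


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of the sorted sample holding ceil(level*N) points."""
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < 2:
        raise ValidationError("need at least 2 samples for an HPD interval")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie in (0, 1)")
    m = int(math.ceil(level * x.size))
    m = min(m, x.size)
    widths = x[m - 1 :] - x[: x.size - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def ess(samples) -> float:
    """Effective sample size, N / (1 + 2 * sum of autocorrelations).

    The autocorrelation sum is truncated at the first non-positive pair sum
    (Geyer's initial positive sequence); the result is clamped to [1, N].
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValidationError("need at least 10 samples for an ESS estimate")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return 1.0
    # FFT autocovariance
    m = 1
    while m < 2 * n:
        m <<= 1
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / var
    tau = 1.0
    t = 1
    cap = math.inf  # Geyer initial monotone sequence
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        cap = min(cap, pair)
        tau += 2.0 * cap
        t += 2
    return float(min(max(n / tau, 1.0), n))
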