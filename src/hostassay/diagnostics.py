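"""Chain summaries: highest-posterior-density intervals and effective sample size."""

from __future__ import annotations

import warnings

import numpy as np


def hpd_interval(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass.

    Computed empirically as the narrowest window covering
    ``ceil(prob * n)`` sorted draws.  For symmetric unimodal samples
    this approximates the central quantile interval.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("cannot form an HPD interval from no draws")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def effective_sample_size(draws) -> float:
    """Effective sample size via Geyer's initial-positive-sequence estimator.

    The autocorrelation time is estimated as ``tau = 2 * sum(Gamma_t) - 1``
    where ``Gamma_t = rho(2t) + rho(2t+1)`` are successive even/odd
    autocorrelation pairs, summed while positive.  Independent draws give
    ESS ~ n (sampling noise can push the estimate slightly above n; it is
    deliberately not truncated).  A constant chain carries no mixing
    information: ESS is reported as n with a warning.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 draws to estimate ESS")
    v = x - x.mean()
    if np.all(v == 0.0):
        warnings.warn("constant chain: reporting ESS = n", stacklevel=2)
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(v, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 0.0
    t = 0
    while 2 * t + 1 < n:
        gamma = rho[2 * t] + rho[2 * t + 1]
        if gamma <= 0.0:
            break
        tau += 2.0 * gamma
        t += 1
    tau -= 1.0
    tau = max(tau, 1.0 / n)
    return float(n / tau)
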