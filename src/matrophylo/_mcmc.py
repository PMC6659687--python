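"""Small shared MCMC utilities."""

from __future__ import annotations

import numpy as np


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the autocorrelation sum, truncated at the first negative
    pair of consecutive autocorrelations (Geyer's initial positive sequence).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
        t += 2
    return float(n / max(1.0, 1.0 + 2.0 * s))


def mc_se(x: np.ndarray) -> float:
    """Monte-Carlo standard error of the mean, ESS-adjusted."""
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(max(effective_sample_size(x), 1.0)))
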