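"""Jitted kernel for the posterior's explained-power fraction.

Grid scans and nested sampling evaluate the marginal posterior tens of
thousands of times per trace; the m x m normal-equations solve is tiny
(m <= ~10), so interpreter overhead dominates unless the whole design ->
Gram -> Cholesky -> solve chain runs in one compiled function.  Results
are identical to the numpy route in core; that route remains the
fallback when numba is unavailable.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def explained_fraction(times, values, omegas, bg_order):
    """m*h2_bar / (N*d2_bar): fraction of data power captured by the model.

    Raises np.linalg.LinAlgError (via Cholesky) for a degenerate basis.
    """
    n = times.size
    r = omegas.size
    mg = bg_order + 1 if bg_order >= 0 else 0
    m = 2 * r + mg
    design = np.empty((n, m))
    for k in range(r):
        w = omegas[k]
        for i in range(n):
            design[i, 2 * k] = np.sin(w * times[i])
            design[i, 2 * k + 1] = np.cos(w * times[i])
    if mg > 0:
        t0 = times[0]
        t1 = times[n - 1]
        base = 2 * r
        for i in range(n):
            tau = 2.0 * (times[i] - t0) / (t1 - t0) - 1.0
            design[i, base] = 1.0
            if mg > 1:
                design[i, base + 1] = tau
            for k in range(1, mg - 1):
                design[i, base + k + 1] = (
                    (2 * k + 1) * tau * design[i, base + k]
                    - k * design[i, base + k - 1]
                ) / (k + 1)
    gram = design.T @ design
    b = design.T @ values
    low = np.linalg.cholesky(gram)
    z = np.empty(m)
    for i in range(m):
        s = b[i]
        for j in range(i):
            s -= low[i, j] * z[j]
        z[i] = s / low[i, i]
    total = 0.0
    for i in range(n):
        total += values[i] * values[i]
    if total == 0.0:
        return 0.0
    explained = 0.0
    for i in range(m):
        explained += z[i] * z[i]
    return explained / total
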