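"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the Hill
oracle is an exhaustive grid search with the amplitude profiled out
analytically, and the conservation oracle is plain fine-step
integration of the algebraic identity.
"""

from __future__ import annotations

import numpy as np


def hill_grid_oracle(s, y, n_grid: int = 200,
                     ka_range=(1e-1, 1e3), n_range=(0.5, 4.0)):
    """Best RSS over a log-grid in (ka, n) with vmax profiled linearly.

    For fixed (ka, n) the model is linear in vmax, so the optimal
    vmax = <h, y> / <h, h> (clipped at 0) with h = s^n/(ka^n + s^n).
    Returns (rss, vmax, ka, n) of the best grid point.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    kas = np.geomspace(*ka_range, n_grid)
    ns = np.geomspace(*n_range, n_grid)
    ka_g, n_g = np.meshgrid(kas, ns, indexing="ij")
    # h has shape (n_grid, n_grid, n_levels)
    h = np.zeros(ka_g.shape + (len(s),))
    for j, sj in enumerate(s):
        if sj > 0:
            sj_n = sj ** n_g
            h[..., j] = sj_n / (ka_g ** n_g + sj_n)
    hh = np.einsum("ijk,ijk->ij", h, h)
    hy = np.einsum("ijk,k->ij", h, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        vmax = np.clip(np.where(hh > 0, hy / hh, 0.0), 0.0, None)
    resid = vmax[..., None] * h - y[None, None, :]
    rss = np.einsum("ijk,ijk->ij", resid, resid)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(rss[i, j]), float(vmax[i, j]), float(kas[i]), float(ns[j])
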