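"""Fused Bloch-Torrey time step (numba): diffusion stencil + phase accrual.

One pass over the lattice applies the explicit 7-point-Laplacian diffusion
update followed by the local precession factor, with periodic wrap, writing
into a second buffer.  Identical arithmetic to the numpy roll-based update,
fused to cut memory traffic for large batches.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bt_step_batch(m, out, phase, d_coef):
    """out = (m + d_coef * lap6(m)) * phase for a (B, nx, ny, nz) batch."""
    nb, nx, ny, nz = m.shape
    for b in range(nb):
        for i in range(nx):
            ip = i + 1 if i + 1 < nx else 0
            im = i - 1 if i > 0 else nx - 1
            for j in range(ny):
                jp = j + 1 if j + 1 < ny else 0
                jm = j - 1 if j > 0 else ny - 1
                for k in range(nz):
                    kp = k + 1 if k + 1 < nz else 0
                    km = k - 1 if k > 0 else nz - 1
                    lap = (
                        m[b, ip, j, k]
                        + m[b, im, j, k]
                        + m[b, i, jp, k]
                        + m[b, i, jm, k]
                        + m[b, i, j, kp]
                        + m[b, i, j, km]
                        - 6.0 * m[b, i, j, k]
                    )
                    out[b, i, j, k] = (m[b, i, j, k] + d_coef * lap) * phase[b, i, j, k]
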