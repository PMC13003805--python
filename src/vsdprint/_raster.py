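"""Tight scan-line tube rasterization kernels (numba).

The center-in test (voxel center within ``radius`` of the tube axis) is
evaluated only inside per-slice bounding slabs of the segment, so the work
scales with the tube volume rather than with its axis-aligned bounding box.
Fine-lattice coordinates follow ``coord(j) = offset + j * hf`` where ``hf``
is the fine voxel size and ``offset = (hf - h_coarse) / 2`` places the
supersampled centers inside the coarse voxels.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _axis_range(lo, hi, offset, hf, n):
    i0 = int(np.ceil((lo - offset) / hf))
    i1 = int(np.floor((hi - offset) / hf))
    if i0 < 0:
        i0 = 0
    if i1 > n - 1:
        i1 = n - 1
    return i0, i1


@njit(cache=True)
def tube_mask_stamp(mask, offset, hf, p0x, p0y, p0z, p1x, p1y, p1z, r, commit):
    """Center-in stamp of one tube into a boolean volume.

    Returns ``(n_new, n_overlap)``: voxels the tube would newly cover and
    voxels already covered.  Writes only when ``commit`` is true.
    """
    nx, ny, nz = mask.shape
    vx, vy, vz = p1x - p0x, p1y - p0y, p1z - p0z
    L2 = vx * vx + vy * vy + vz * vz
    m = r + hf
    r2 = r * r
    n_new = 0
    n_old = 0
    ix0, ix1 = _axis_range(min(p0x, p1x) - m, max(p0x, p1x) + m, offset, hf, nx)
    for ix in range(ix0, ix1 + 1):
        x = offset + ix * hf
        if abs(vx) > 1e-12:
            ta = (x - m - p0x) / vx
            tb = (x + m - p0x) / vx
            tlo = min(ta, tb)
            thi = max(ta, tb)
            if tlo < 0.0:
                tlo = 0.0
            if thi > 1.0:
                thi = 1.0
            if tlo > thi:
                continue
        else:
            if abs(x - p0x) > m:
                continue
            tlo, thi = 0.0, 1.0
        ya = p0y + tlo * vy
        yb = p0y + thi * vy
        iy0, iy1 = _axis_range(min(ya, yb) - m, max(ya, yb) + m, offset, hf, ny)
        za = p0z + tlo * vz
        zb = p0z + thi * vz
        iz0, iz1 = _axis_range(min(za, zb) - m, max(za, zb) + m, offset, hf, nz)
        for iy in range(iy0, iy1 + 1):
            y = offset + iy * hf
            for iz in range(iz0, iz1 + 1):
                z = offset + iz * hf
                dx = x - p0x
                dy = y - p0y
                dz = z - p0z
                if L2 > 0.0:
                    t = (dx * vx + dy * vy + dz * vz) / L2
                    if t < 0.0:
                        t = 0.0
                    elif t > 1.0:
                        t = 1.0
                    dx -= t * vx
                    dy -= t * vy
                    dz -= t * vz
                if dx * dx + dy * dy + dz * dz <= r2:
                    if mask[ix, iy, iz]:
                        n_old += 1
                    else:
                        n_new += 1
                        if commit:
                            mask[ix, iy, iz] = True
    return n_new, n_old


@njit(cache=True)
def tube_owner_stamp(owner, offset, hf, p0x, p0y, p0z, p1x, p1y, p1z, r, idx):
    """First-writer-wins owner assignment (callers stamp in priority order)."""
    nx, ny, nz = owner.shape
    vx, vy, vz = p1x - p0x, p1y - p0y, p1z - p0z
    L2 = vx * vx + vy * vy + vz * vz
    m = r + hf
    r2 = r * r
    ix0, ix1 = _axis_range(min(p0x, p1x) - m, max(p0x, p1x) + m, offset, hf, nx)
    for ix in range(ix0, ix1 + 1):
        x = offset + ix * hf
        if abs(vx) > 1e-12:
            ta = (x - m - p0x) / vx
            tb = (x + m - p0x) / vx
            tlo = min(ta, tb)
            thi = max(ta, tb)
            if tlo < 0.0:
                tlo = 0.0
            if thi > 1.0:
                thi = 1.0
            if tlo > thi:
                continue
        else:
            if abs(x - p0x) > m:
                continue
            tlo, thi = 0.0, 1.0
        ya = p0y + tlo * vy
        yb = p0y + thi * vy
        iy0, iy1 = _axis_range(min(ya, yb) - m, max(ya, yb) + m, offset, hf, ny)
        za = p0z + tlo * vz
        zb = p0z + thi * vz
        iz0, iz1 = _axis_range(min(za, zb) - m, max(za, zb) + m, offset, hf, nz)
        for iy in range(iy0, iy1 + 1):
            y = offset + iy * hf
            for iz in range(iz0, iz1 + 1):
                if owner[ix, iy, iz] >= 0:
                    continue
                z = offset + iz * hf
                dx = x - p0x
                dy = y - p0y
                dz = z - p0z
                if L2 > 0.0:
                    t = (dx * vx + dy * vy + dz * vz) / L2
                    if t < 0.0:
                        t = 0.0
                    elif t > 1.0:
                        t = 1.0
                    dx -= t * vx
                    dy -= t * vy
                    dz -= t * vz
                if dx * dx + dy * dy + dz * dz <= r2:
                    owner[ix, iy, iz] = idx
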