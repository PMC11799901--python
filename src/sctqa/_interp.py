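"""Numba kernel for affine trilinear resampling of 3D grids.

Used by the positioning module, where a rigid-pose resample sits inside the
registration objective and is evaluated hundreds of times per solve.
Matches the usual convention: output voxel (i, j, k) samples the input at
``A @ (i, j, k) + b`` (fractional input index), constant fill outside.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def affine_trilinear(src, a, b, out_shape, cval):  # pragma: no cover - jitted
    nx, ny, nz = src.shape
    mx, my, mz = out_shape
    out = np.empty((mx, my, mz))
    for i in range(mx):
        for j in range(my):
            for k in range(mz):
                x = a[0, 0] * i + a[0, 1] * j + a[0, 2] * k + b[0]
                y = a[1, 0] * i + a[1, 1] * j + a[1, 2] * k + b[1]
                z = a[2, 0] * i + a[2, 1] * j + a[2, 2] * k + b[2]
                if x < -1.0 or x > nx or y < -1.0 or y > ny or z < -1.0 or z > nz:
                    out[i, j, k] = cval
                    continue
                x0 = int(np.floor(x))
                y0 = int(np.floor(y))
                z0 = int(np.floor(z))
                fx = x - x0
                fy = y - y0
                fz = z - z0
                acc = 0.0
                for dx in range(2):
                    wx = fx if dx == 1 else 1.0 - fx
                    if wx == 0.0:
                        continue
                    xi = x0 + dx
                    for dy in range(2):
                        wy = fy if dy == 1 else 1.0 - fy
                        if wy == 0.0:
                            continue
                        yj = y0 + dy
                        for dz in range(2):
                            wz = fz if dz == 1 else 1.0 - fz
                            if wz == 0.0:
                                continue
                            zk = z0 + dz
                            if 0 <= xi < nx and 0 <= yj < ny and 0 <= zk < nz:
                                v = src[xi, yj, zk]
                            else:
                                v = cval
                            acc += wx * wy * wz * v
                out[i, j, k] = acc
    return out
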