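"""Independent brute-force oracles used by multiple test modules.

Deliberately written as slow per-pixel loops, independent of the
package's vectorized implementations.
"""

import numpy as np


def mirror_index(idx, n):
    if n == 1:
        return 0
    period = 2 * n - 2
    m = idx % period
    return m if m < n else period - m


def brute_force_triplanar(volume, voxel, spec):
    """Direct slicing oracle for triplanar multiscale patch extraction."""
    p = spec.patch_edge
    r = (p - 1) // 2
    planes = ((0, 1, 2), (1, 0, 2), (2, 0, 1))
    out = np.empty((6, p, p))
    for si, scale in enumerate(spec.scales):
        for pi, (fax, rax, cax) in enumerate(planes):
            for i in range(p):
                for j in range(p):
                    idx = [0, 0, 0]
                    idx[fax] = int(voxel[fax])
                    idx[rax] = mirror_index(
                        int(voxel[rax]) + int(scale) * (i - r), volume.shape[rax]
                    )
                    idx[cax] = mirror_index(
                        int(voxel[cax]) + int(scale) * (j - r), volume.shape[cax]
                    )
                    out[si * 3 + pi, i, j] = volume[tuple(idx)]
    return out
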