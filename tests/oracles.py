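"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — explicit voxel iteration, brute-force
BFS, direct formula evaluation — and shares no code with the package paths it
checks.
"""

from collections import defaultdict, deque

import numpy as np


def rand_score_by_iteration(gt, pred, alpha=0.5, foreground_restricted=True):
    """RAND F-score by explicit voxel iteration over the flattened volumes."""
    joint = defaultdict(int)
    n = 0
    for g, p in zip(np.asarray(gt).ravel().tolist(), np.asarray(pred).ravel().tolist()):
        if foreground_restricted and g == 0:
            continue
        joint[(p, g)] += 1
        n += 1
    if n == 0:
        raise ValueError("empty evaluation")
    s = defaultdict(float)
    t = defaultdict(float)
    sum_p2 = 0.0
    for (p, g), c in joint.items():
        pij = c / n
        sum_p2 += pij * pij
        s[p] += pij
        t[g] += pij
    sum_s2 = sum(v * v for v in s.values())
    sum_t2 = sum(v * v for v in t.values())
    return sum_p2 / (alpha * sum_s2 + (1 - alpha) * sum_t2)


_STENCILS = {
    6: [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
    26: [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
}


def bfs_label(mask, connectivity):
    """Brute-force BFS connected-component labeling over a boolean volume."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    stencil = _STENCILS[connectivity]
    nz, ny, nx = mask.shape
    nxt = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or out[z, y, x]:
                    continue
                nxt += 1
                out[z, y, x] = nxt
                q = deque([(z, y, x)])
                while q:
                    cz, cy, cx = q.popleft()
                    for dz, dy, dx in stencil:
                        az, ay, ax = cz + dz, cy + dy, cx + dx
                        if 0 <= az < nz and 0 <= ay < ny and 0 <= ax < nx:
                            if mask[az, ay, ax] and not out[az, ay, ax]:
                                out[az, ay, ax] = nxt
                                q.append((az, ay, ax))
    return out


def labelings_equivalent(a, b):
    """True when two labelings are identical up to an id permutation."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if ((a == 0) != (b == 0)).any():
        return False
    fwd, bwd = {}, {}
    for x, y in zip(a.tolist(), b.tolist()):
        if fwd.setdefault(x, y) != y or bwd.setdefault(y, x) != x:
            return False
    return True


def equalize_block(block, bins, vmax):
    """Classic full histogram equalization of one tile (no clipping)."""
    idx = (block.astype(np.int64) * bins) // (vmax + 1)
    hist = np.bincount(idx.ravel(), minlength=bins).astype(float)
    cdf = np.cumsum(hist)
    cdfmin = cdf[np.argmax(hist > 0)]
    denom = block.size - cdfmin
    lut = np.clip((cdf - cdfmin) / denom * vmax, 0, vmax)
    return lut, idx
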