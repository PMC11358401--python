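"""Independent brute-force reference implementations used only by tests."""

import itertools

import numpy as np


def kmeans_1d_exact(values, k):
    """Optimal 1-D k-means by enumerating contiguous partitions of sorted values.

    Returns the within-cluster sum of squares and the assignment (cluster
    rank by ascending mean) for each input value.  Exponential; tiny n only.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = len(v)
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        wcss = 0.0
        assign_sorted = np.empty(n, dtype=int)
        for c in range(k):
            seg = v[bounds[c]: bounds[c + 1]]
            wcss += float(np.sum((seg - seg.mean()) ** 2))
            assign_sorted[bounds[c]: bounds[c + 1]] = c
        if wcss < best[0] - 1e-12:
            best = (wcss, assign_sorted)
    assign = np.empty(n, dtype=int)
    assign[order] = best[1]
    return best[0], assign


def closing_bruteforce(mask, se):
    """Dilation followed by erosion, evaluated voxel by voxel on a padded frame."""
    mask = np.asarray(mask, dtype=bool)
    r = se.shape[0] // 2
    offsets = np.argwhere(se) - r
    pad = np.pad(mask, 2 * r)

    def dilate(m):
        out = np.zeros_like(m)
        for idx in np.argwhere(m):
            for off in offsets:
                out[tuple(idx + off)] = True
        return out

    def erode(m):
        out = np.zeros_like(m)
        for idx in np.argwhere(m):
            if all(m[tuple(idx + off)] for off in offsets):
                out[tuple(idx)] = True
        return out

    closed = erode(dilate(pad))
    sl = tuple(slice(2 * r, 2 * r + s) for s in mask.shape)
    return closed[sl]


def dice_bruteforce(a, b, ids):
    sa = {tuple(i) for i in np.argwhere(np.isin(a, list(ids)))}
    sb = {tuple(i) for i in np.argwhere(np.isin(b, list(ids)))}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def ahd_bruteforce(points_a, points_b):
    """All-pairs symmetric mean nearest-neighbour distance (mm point sets)."""
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def mirror_shift_gridsearch(x_coords, alpha, lo, hi, step=0.01):
    """Dense 1-D search over the x-shift of the mirror-placement cost."""
    x = np.asarray(x_coords, dtype=float)
    shifts = np.arange(lo, hi + step / 2, step)
    best_t, best_c = None, np.inf
    for t in shifts:
        xt = x + t
        c = xt[xt > 0].sum() - alpha * xt.sum()
        if c < best_c:
            best_c, best_t = c, t
    return best_t, best_c
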