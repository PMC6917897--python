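"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorised code paths: plain Python
loops over the definitions, kept simple enough to verify by eye.
"""

from __future__ import annotations

import numpy as np


def brute_force_es(scores, hit_mask, p=1.0):
    """Running-sum enrichment score by direct walk; returns (es, running)."""
    scores = np.asarray(scores, float)
    hit_mask = np.asarray(hit_mask, bool)
    N = len(scores)
    NH = int(hit_mask.sum())
    w = np.abs(scores) ** p
    NR = float(w[hit_mask].sum())
    run = 0.0
    values = []
    for i in range(N):
        if hit_mask[i]:
            run += w[i] / NR
        else:
            run -= 1.0 / (N - NH)
        values.append(run)
    hi = max(max(values), 0.0)
    lo = min(min(values), 0.0)
    es = hi if hi >= -lo else lo
    return es, np.array(values)


def brute_force_ks(hit_ranks, miss_ranks):
    """Two-sample KS statistic between hit and miss rank positions."""
    hit_ranks = sorted(hit_ranks)
    miss_ranks = sorted(miss_ranks)
    n_h, n_m = len(hit_ranks), len(miss_ranks)
    best = 0.0
    for t in sorted(set(hit_ranks) | set(miss_ranks)):
        f_h = sum(r <= t for r in hit_ranks) / n_h
        f_m = sum(r <= t for r in miss_ranks) / n_m
        best = max(best, abs(f_h - f_m))
    return best


def rasterize_sphere_union(shape, voxel_size, foci):
    """Count voxels strictly inside the union of spheres (center_mm, radius)."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                pos = np.array([i, j, k]) * voxel_size
                for center, radius in foci:
                    if np.linalg.norm(pos - np.asarray(center)) < radius:
                        count += 1
                        break
    return count
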