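"""Independent brute-force oracles used to check the implementation.

Everything here is written naively (explicit loops, direct formulas) and never
imports the code paths it is used to verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def l1_ball_indices(center: tuple[int, int, int], radius: int, dims: tuple[int, int, int]):
    """All in-bounds voxels within L1 (city-block) distance ``radius`` of center."""
    out = set()
    cx, cy, cz = center
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                if abs(i - cx) + abs(j - cy) + abs(k - cz) <= radius:
                    out.add((i, j, k))
    return out


def brute_sphere_offsets(radius_mm: float, voxel_mm, window: int = 5):
    """Enumerate integer offsets within a physical radius by scanning a window."""
    dx, dy, dz = voxel_mm
    out = []
    for i in range(-window, window + 1):
        for j in range(-window, window + 1):
            for k in range(-window, window + 1):
                if math.sqrt((i * dx) ** 2 + (j * dy) ** 2 + (k * dz) ** 2) <= radius_mm:
                    out.append((i, j, k))
    return sorted(out)


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    return float((ac * bc).sum() / math.sqrt((ac * ac).sum() * (bc * bc).sum()))


def triple_loop_difference_map(series, peri_voxels, grid_dims, lr_axis, offsets, target_mask):
    """Voxel-by-voxel reference implementation of the difference map.

    ``series``: ndarray (nx, ny, nz, T); ``target_mask``: boolean ndarray.
    Mirrors each perilesional voxel across the mid-grid plane, averages
    sphere∩target series, correlates against every target voxel, applies
    atanh with the same 1e-7 clip, and averages.  Returns (entries, metric).
    """
    clip = 1.0 - 1e-7
    targets = [
        (i, j, k)
        for i in range(grid_dims[0])
        for j in range(grid_dims[1])
        for k in range(grid_dims[2])
        if target_mask[i, j, k]
    ]

    def sphere_mean(voxel):
        vals = []
        for off in offsets:
            p = [voxel[0] + off[0], voxel[1] + off[1], voxel[2] + off[2]]
            if all(0 <= p[d] < grid_dims[d] for d in range(3)) and target_mask[tuple(p)]:
                vals.append(series[tuple(p)])
        return np.mean(np.asarray(vals), axis=0)

    def mean_z(ts):
        zs = []
        for t in targets:
            v = series[t]
            if np.std(v) == 0 or np.std(ts) == 0:
                zs.append(0.0)
                continue
            r = pearson(ts, v)
            zs.append(math.atanh(max(-clip, min(clip, r))))
        return float(np.mean(zs))

    entries = {}
    for voxel in peri_voxels:
        mirrored = list(voxel)
        mirrored[lr_axis] = grid_dims[lr_axis] - 1 - mirrored[lr_axis]
        mirrored = tuple(mirrored)
        z_p = mean_z(sphere_mean(voxel))
        z_c = mean_z(sphere_mean(mirrored))
        entries[tuple(voxel)] = z_p - z_c
    metric = float(np.mean(list(entries.values())))
    return entries, metric


def exact_mann_whitney(a, b):
    """Full-enumeration two-tailed Mann-Whitney p with midranks.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes; returns (U for group a, two-tailed p as
    2 * min(P(U <= u), P(U >= u)) capped at 1).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n, m = len(a), len(b)

    def midranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = r
            i = j + 1
        return ranks

    ranks = midranks(pooled)
    u_obs = sum(ranks[:n]) - n * (n + 1) / 2.0
    us = []
    for comb in itertools.combinations(range(n + m), n):
        us.append(sum(ranks[i] for i in comb) - n * (n + 1) / 2.0)
    tol = 1e-9
    p_le = sum(u <= u_obs + tol for u in us) / len(us)
    p_ge = sum(u >= u_obs - tol for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def spearman_closed_form(x, y):
    """1 - 6 sum(d^2) / (n (n^2 - 1)) for untied data."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))
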