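"""Independent brute-force reference implementations used only by tests.

Pure-Python loops, deliberately naive: per-voxel neighbor enumeration for
the co-occurrence and grey-tone-difference matrices, breadth-first flood
fill for zones, and a risk-table walk for the log-rank statistic.  They
share no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

HALF_DIRECTIONS = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
]
ALL_DIRECTIONS = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def brute_glcm(levels: np.ndarray, ng: int, distance: int = 1, symmetric: bool = True):
    """Pair counts by explicit enumeration of every voxel and direction."""
    counts = np.zeros((ng, ng), dtype=np.int64)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for dx, dy, dz in HALF_DIRECTIONS:
                    u, v, w = x + dx * distance, y + dy * distance, z + dz * distance
                    if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                        continue
                    b = levels[u, v, w]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    if symmetric:
                        counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts, (counts / total if total else counts.astype(float))


def brute_ngtdm(levels: np.ndarray, ng: int):
    """Per-voxel neighborhood averages by explicit 26-neighbor loops."""
    nx, ny, nz = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=np.int64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lev = levels[x, y, z]
                if lev == 0:
                    continue
                neigh = []
                for dx, dy, dz in ALL_DIRECTIONS:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and levels[u, v, w] > 0:
                        neigh.append(levels[u, v, w])
                if not neigh:
                    continue
                s[lev - 1] += abs(lev - sum(neigh) / len(neigh))
                n[lev - 1] += 1
    return s, n


def brute_glzm(levels: np.ndarray, ng: int):
    """Zones by breadth-first flood fill under 26-connectivity."""
    nx, ny, nz = levels.shape
    seen = np.zeros_like(levels, dtype=bool)
    zones: list[tuple[int, int]] = []  # (level, size)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lev = levels[x, y, z]
                if lev == 0 or seen[x, y, z]:
                    continue
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx, dy, dz in ALL_DIRECTIONS:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                            and not seen[u, v, w] and levels[u, v, w] == lev
                        ):
                            seen[u, v, w] = True
                            queue.append((u, v, w))
                zones.append((lev, size))
    zmax = max((sz for _, sz in zones), default=1)
    P = np.zeros((ng, zmax), dtype=np.int64)
    for lev, sz in zones:
        P[lev - 1, sz - 1] += 1
    return P


def brute_logrank(times_a, events_a, times_b, events_b):
    """Observed/expected accumulation over explicitly enumerated risk sets."""
    ta, ea = list(times_a), list(events_a)
    tb, eb = list(times_b), list(events_b)
    death_times = sorted({t for t, e in zip(ta + tb, ea + eb) if e == 1})
    oa = ea_sum = var = ob = eb_sum = 0.0
    for t in death_times:
        na = sum(1 for x in ta if x >= t)
        nb = sum(1 for x in tb if x >= t)
        n = na + nb
        da = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        db = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        d = da + db
        oa += da
        ob += db
        ea_sum += d * na / n
        eb_sum += d * nb / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = (oa - ea_sum) ** 2 / var if var > 0 else 0.0
    return chi2, (oa, ea_sum), (ob, eb_sum)


def brute_holm(p_raw, alpha=0.05):
    """Direct step-down evaluation: p_adj(k) = max_{j<=k} min(1, (m-j+1) p_(j))."""
    m = len(p_raw)
    order = sorted(range(m), key=lambda k: p_raw[k])
    p_adj = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_raw[idx]))
        p_adj[idx] = running
    reject = [False] * m
    for rank, idx in enumerate(order):
        if p_adj[idx] < alpha:
            reject[idx] = True
        else:
            break
    return p_adj, reject


def brute_spearman_rho(x, y):
    """Rank correlation as Pearson correlation of average ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda k: v[k])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
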