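"""Independent brute-force oracles for the texture engine.

Everything here is written with explicit Python loops and containers —
pair listing for the co-occurrence matrix, voxel-by-voxel run walking for
the run-length matrix, breadth-first flood fill for zones, and direct
formula evaluation for the indices — deliberately sharing no code with the
package's vectorized implementation.
"""

from __future__ import annotations

import math
from collections import deque


def bf_directions():
    dirs = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                if (a, b, c) == (0, 0, 0):
                    continue
                if (-a, -b, -c) in dirs:
                    continue
                dirs.append((a, b, c))
    return dirs


def _in(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


def bf_cm(levels, mask, d):
    """Symmetric co-occurrence probabilities as a dict {(i, j): p}."""
    shape = levels.shape
    counts = {}
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                q = (x + d[0], y + d[1], z + d[2])
                if not _in(shape, q) or not mask[q]:
                    continue
                i, j = int(levels[x, y, z]), int(levels[q])
                counts[(i, j)] = counts.get((i, j), 0) + 1
                counts[(j, i)] = counts.get((j, i), 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()} if total else {}


def bf_cm_indices(prob):
    homo = sum(p / (1 + abs(i - j)) for (i, j), p in prob.items())
    ent = -sum(p * math.log2(p) for p in prob.values() if p > 0)
    contr = sum(p * (i - j) ** 2 for (i, j), p in prob.items())
    return homo, ent, contr


def bf_runs(levels, mask, d):
    """List of (gray level, run length) for maximal runs along direction d."""
    shape = levels.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if (
                    _in(shape, prev)
                    and mask[prev]
                    and levels[prev] == levels[x, y, z]
                ):
                    continue  # not a run start
                length = 1
                cur = (x, y, z)
                while True:
                    nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    if (
                        _in(shape, nxt)
                        and mask[nxt]
                        and levels[nxt] == levels[x, y, z]
                    ):
                        length += 1
                        cur = nxt
                    else:
                        break
                runs.append((int(levels[x, y, z]), length))
    return runs


def bf_grlm_indices(runs):
    h = len(runs)
    sre = sum(1.0 / (j * j) for _, j in runs) / h
    lre = sum(float(j * j) for _, j in runs) / h
    by_length = {}
    for _, j in runs:
        by_length[j] = by_length.get(j, 0) + 1
    rlnu = sum(c * c for c in by_length.values()) / h
    return sre, lre, rlnu


def bf_zones(levels, mask, connectivity=26):
    """List of (gray level, size) for connected equal-level zones."""
    shape = levels.shape
    if connectivity == 26:
        neigh = [
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = set()
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or (x, y, z) in seen:
                    continue
                g = int(levels[x, y, z])
                queue = deque([(x, y, z)])
                seen.add((x, y, z))
                size = 0
                while queue:
                    p = queue.popleft()
                    size += 1
                    for dd in neigh:
                        q = (p[0] + dd[0], p[1] + dd[1], p[2] + dd[2])
                        if (
                            _in(shape, q)
                            and q not in seen
                            and mask[q]
                            and int(levels[q]) == g
                        ):
                            seen.add(q)
                            queue.append(q)
                zones.append((g, size))
    return zones


def bf_gzlm_indices(zones):
    h = len(zones)
    lgze = sum(1.0 / (g * g) for g, _ in zones) / h
    hgze = sum(float(g * g) for g, _ in zones) / h
    return lgze, hgze
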