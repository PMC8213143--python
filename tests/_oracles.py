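"""Independent brute-force oracles for texture matrices, features and stats.

Everything here is written as plain Python loops, deliberately sharing no
code with the package implementation, so agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def all_neighbor_offsets(ndim):
    """All (3^ndim - 1) nonzero unit-chebyshev offsets."""
    out = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if any(off):
            out.append(off)
    return out


def half_neighbor_offsets(ndim):
    """Unique directions: first nonzero component positive."""
    out = []
    for off in all_neighbor_offsets(ndim):
        first = next(v for v in off if v != 0)
        if first > 0:
            out.append(off)
    return out


def oracle_glcm(grid, directions=None, distance=1):
    """Symmetric merged co-occurrence probabilities by explicit pair listing.

    ``grid`` holds grey levels >= 1 inside the mask and 0 outside.
    Returns an (ng, ng) probability array indexed by level-1.
    """
    grid = np.asarray(grid)
    if directions is None:
        directions = half_neighbor_offsets(grid.ndim)
    ng = int(grid.max())
    counts = np.zeros((ng, ng))
    for pos in itertools.product(*(range(n) for n in grid.shape)):
        a = grid[pos]
        if a == 0:
            continue
        for d in directions:
            nb = tuple(p + distance * dd for p, dd in zip(pos, d))
            if any(q < 0 or q >= n for q, n in zip(nb, grid.shape)):
                continue
            b = grid[nb]
            if b == 0:
                continue
            counts[a - 1, b - 1] += 1  # ordering pos -> nb
            counts[b - 1, a - 1] += 1  # and the reverse ordering
    total = counts.sum()
    return counts / total if total else counts


def oracle_glrlm(grid, directions=None):
    """Run counts by walking every maximal run voxel by voxel."""
    grid = np.asarray(grid)
    if directions is None:
        directions = half_neighbor_offsets(grid.ndim)
    runs = Counter()
    rmax = 1
    for d in directions:
        for pos in itertools.product(*(range(n) for n in grid.shape)):
            lvl = grid[pos]
            if lvl == 0:
                continue
            prev = tuple(p - dd for p, dd in zip(pos, d))
            in_prev = all(0 <= q < n for q, n in zip(prev, grid.shape))
            if in_prev and grid[prev] == lvl:
                continue  # not a run start
            length = 1
            cur = pos
            while True:
                nxt = tuple(p + dd for p, dd in zip(cur, d))
                if not all(0 <= q < n for q, n in zip(nxt, grid.shape)):
                    break
                if grid[nxt] != lvl:
                    break
                length += 1
                cur = nxt
            runs[(int(lvl), length)] += 1
            rmax = max(rmax, length)
    ng = int(grid.max())
    counts = np.zeros((ng, rmax))
    for (g, r), c in runs.items():
        counts[g - 1, r - 1] = c
    return counts


def oracle_glszm(grid):
    """Zone counts by flood fill over full-neighborhood connectivity."""
    grid = np.asarray(grid)
    offsets = all_neighbor_offsets(grid.ndim)
    seen = np.zeros(grid.shape, dtype=bool)
    zones = Counter()
    smax = 1
    for pos in itertools.product(*(range(n) for n in grid.shape)):
        if grid[pos] == 0 or seen[pos]:
            continue
        lvl = int(grid[pos])
        stack = [pos]
        seen[pos] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in offsets:
                nb = tuple(p + dd for p, dd in zip(cur, d))
                if not all(0 <= q < n for q, n in zip(nb, grid.shape)):
                    continue
                if seen[nb] or grid[nb] != lvl:
                    continue
                seen[nb] = True
                stack.append(nb)
        zones[(lvl, size)] += 1
        smax = max(smax, size)
    ng = int(grid.max())
    counts = np.zeros((ng, smax))
    for (g, s), c in zones.items():
        counts[g - 1, s - 1] = c
    return counts


def oracle_glcm_features(p):
    """The 18 co-occurrence features by naive double loops."""
    p = np.asarray(p, dtype=float)
    ng = p.shape[0]
    f = {}
    f["JMax"] = max(p[i, j] for i in range(ng) for j in range(ng))
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    f["JointAverage"] = mu
    f["JVar"] = sum((i + 1 - mu) ** 2 * p[i, j]
                    for i in range(ng) for j in range(ng))
    f["JEntropy"] = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    pd_ = [0.0] * ng
    ps_ = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pd_[abs(i - j)] += p[i, j]
            ps_[i + j] += p[i, j]
    da = sum(k * pd_[k] for k in range(ng))
    f["Dissim"] = da
    f["DifferenceVariance"] = sum((k - da) ** 2 * pd_[k] for k in range(ng))
    f["DifferenceEntropy"] = -sum(
        q * math.log2(q) for q in pd_ if q > 0
    )
    sa = sum((k + 2) * ps_[k] for k in range(2 * ng - 1))
    f["SumAverage"] = sa
    f["SumVar"] = sum((k + 2 - sa) ** 2 * ps_[k] for k in range(2 * ng - 1))
    f["SumEntropy"] = -sum(q * math.log2(q) for q in ps_ if q > 0)
    f["AngularSecondMoment"] = sum(
        p[i, j] ** 2 for i in range(ng) for j in range(ng)
    )
    f["Contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    # marginal variance (symmetric matrix): E[(i-mu)^2] over the row marginal
    var_i = sum(
        (i + 1 - mu) ** 2 * sum(p[i, j] for j in range(ng)) for i in range(ng)
    )
    if var_i > 0:
        f["Correlation"] = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i, j]
            for i in range(ng) for j in range(ng)
        ) / var_i
    else:
        f["Correlation"] = 0.0
    for power, name in ((2, "ClusterTendency"), (3, "ClusterShade"),
                        (4, "ClusterProm")):
        f[name] = sum(
            (i + 1 + j + 1 - 2 * mu) ** power * p[i, j]
            for i in range(ng) for j in range(ng)
        )
    f["InverseDifference"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    f["NormInvDiff"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    return f


def oracle_rlm_features(counts, n_voxels, n_directions, kind):
    """Run-length or size-zone features by naive loops.

    kind "rlm" uses names SRE..RP and denominator n_voxels * n_directions
    for the percentage; kind "szm" uses SZE..ZP with denominator n_voxels.
    """
    counts = np.asarray(counts, dtype=float)
    ng, rmax = counts.shape
    ns = counts.sum()
    terms = {
        "sr": 0.0, "lr": 0.0, "lg": 0.0, "hg": 0.0,
        "srlg": 0.0, "srhg": 0.0, "lrlg": 0.0, "lrhg": 0.0,
    }
    for gi in range(ng):
        for ri in range(rmax):
            c = counts[gi, ri]
            if c == 0:
                continue
            g, r = gi + 1, ri + 1
            terms["sr"] += c / r**2
            terms["lr"] += c * r**2
            terms["lg"] += c / g**2
            terms["hg"] += c * g**2
            terms["srlg"] += c / (g**2 * r**2)
            terms["srhg"] += c * g**2 / r**2
            terms["lrlg"] += c * r**2 / g**2
            terms["lrhg"] += c * g**2 * r**2
    glnu = sum(counts[gi, :].sum() ** 2 for gi in range(ng)) / ns
    rlnu = sum(counts[:, ri].sum() ** 2 for ri in range(rmax)) / ns
    if kind == "rlm":
        names = ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE",
                 "LRHGE", "GLNU", "RLNU", "RP"]
        pct = ns / (n_voxels * n_directions)
    else:
        names = ["SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE",
                 "LZHGE", "GLNUz", "ZSNU", "ZP"]
        pct = ns / n_voxels
    vals = [terms[k] / ns for k in
            ("sr", "lr", "lg", "hg", "srlg", "srhg", "lrlg", "lrhg")]
    vals += [glnu, rlnu, pct]
    return dict(zip(names, vals))


def oracle_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    n1, n = len(x), len(x) + len(y)
    ranks = {}
    # average ranks for ties
    vals = pooled
    i = 0
    rank_of = [0.0] * n
    while i < n:
        j = i
        while j < n and vals[j] == vals[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            rank_of[k] = avg
        i = j
    # map each observation to its rank (consume duplicates in order)
    remaining = list(zip(vals, rank_of))

    def take_rank(v):
        for idx, (vv, rr) in enumerate(remaining):
            if vv == v:
                remaining.pop(idx)
                return rr
        raise AssertionError

    w_obs = sum(take_rank(v) for v in x)
    all_ranks = rank_of
    mean_w = n1 * (n + 1) / 2.0
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        w = sum(all_ranks[i] for i in combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            extreme += 1
    return extreme / total
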