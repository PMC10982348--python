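"""Independent brute-force oracles shared by unit and acceptance tests.

Deliberately naive (explicit Python loops, no shared code with the package)
so they can certify the vectorised implementations.
"""

import math

import numpy as np


def brute_local_maxima(a):
    """Exhaustive scan of interior strict maxima with plateau-first-index."""
    out = []
    n = len(a)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and a[j + 1] == a[i]:
            j += 1
        if a[i] > a[i - 1] and j + 1 < n and a[i] > a[j + 1]:
            out.append(i)
        i = j + 1
    return out


def brute_best_pair(a, peaks, sep_lo, sep_hi):
    """Exhaustively score all admissible candidate pairs of one A-scan."""
    best = None
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            y1, y2 = int(peaks[i]), int(peaks[j])
            if not (sep_lo <= y2 - y1 <= sep_hi):
                continue
            score = abs(a[y1] - a[y2]) - min(a[y1 : y2 + 1])
            key = (score, -min(y1, y2))
            if best is None or key > best[0]:
                best = (key, (y1, y2, score))
    return None if best is None else best[1]


def oracle_refine(absg, base, valid, p, r):
    """Naive re-implementation of the centre-out refinement scoring rule.

    Seed at the central valid column, rigid shift of the committed profile,
    ``w(d) = p (1-p)^d`` with ``d`` = column distance minus one, truncation
    below ``1e-6 w(0)``, ties to the first (shallowest) offset.  Returns
    per-column refined rows and winning scores.
    """
    y_dim, x_dim = absg.shape
    cols = [x for x in range(x_dim) if valid[x]]
    centre = min(cols, key=lambda x: (abs(x - (x_dim - 1) / 2), x))
    horizon = max(1, math.ceil(math.log(1e-6) / math.log(1 - p)))

    refined, offsets, scores = {}, {}, {}

    def clamp(y):
        return min(max(y, 0), y_dim - 1)

    best_score, best_delta = None, None
    for delta in range(-r, r + 1):
        s = absg[clamp(base[centre] + delta), centre]
        if best_score is None or s > best_score:
            best_score, best_delta = s, delta
    offsets[centre] = best_delta
    refined[centre] = clamp(base[centre] + best_delta)
    scores[centre] = best_score

    for side in ([x for x in cols if x > centre], [x for x in cols if x < centre][::-1]):
        committed = [centre]
        for x in side:
            best_score, best_delta = None, None
            for delta in range(-r, r + 1):
                s = absg[clamp(base[x] + delta), x]
                for xj in committed:
                    d = abs(x - xj) - 1
                    if d > horizon:
                        continue
                    w = p * (1 - p) ** d
                    row = clamp(refined[xj] + delta - offsets[xj])
                    s += w * absg[row, xj]
                if best_score is None or s > best_score:
                    best_score, best_delta = s, delta
            offsets[x] = best_delta
            refined[x] = clamp(base[x] + best_delta)
            scores[x] = best_score
            committed.append(x)
    return refined, scores


def bfs_distances(mask, seed):
    """Shortest 4-connected path lengths via networkx (independent oracle)."""
    import networkx as nx

    g = nx.Graph()
    rows, cols = mask.shape
    for v in range(rows):
        for u in range(cols):
            if not mask[v, u]:
                continue
            g.add_node((v, u))
            for dv, du in ((1, 0), (0, 1)):
                nv, nu = v + dv, u + du
                if nv < rows and nu < cols and mask[nv, nu]:
                    g.add_edge((v, u), (nv, nu))
    return nx.single_source_shortest_path_length(g, seed)
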