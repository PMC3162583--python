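"""Independent brute-force oracles used to validate the optimized implementations.

Each oracle deliberately takes a different computational route from the code
under test: pair-by-pair enumeration for the tau decomposition, exhaustive
monotone-matching enumeration for local alignment, and a naive
recompute-everything agglomeration for Ward clustering.
"""

from __future__ import annotations

import numpy as np


def kendall_decomposition_enumeration(x, y):
    """Tau-a distance and per-feature contributions by explicit pair enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = x.size
    contrib = np.zeros(m)
    s_total = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
            s_total += s
            share = (1.0 - s) / (2.0 * m * (m - 1))
            contrib[i] += share
            contrib[j] += share
    tau = 2.0 * s_total / (m * (m - 1))
    return (1.0 - tau) / 2.0, contrib


def brute_force_local_alignment(mirna: str, window: str, params) -> float:
    """Best local-alignment score by enumerating all monotone matchings.

    An alignment is a non-empty set of matched position pairs, increasing in
    both sequences; unmatched stretches between consecutive matched pairs are
    charged as affine gaps in each sequence independently.  Exponential, so
    only usable on short instances.
    """
    m = str(mirna).upper().replace("T", "U")
    w = str(window).upper().replace("T", "U")[::-1]
    n, L = len(m), len(w)

    def gapcost(g: int) -> float:
        return 0.0 if g == 0 else params.gap_open + (g - 1) * params.gap_extend

    pair = [[params.pair_score(m[i], w[j], i + 1) for j in range(L)] for i in range(n)]
    best = 0.0

    def rec(i: int, j: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        for i2 in range(i + 1, n):
            for j2 in range(j + 1, L):
                rec(
                    i2,
                    j2,
                    score + gapcost(i2 - i - 1) + gapcost(j2 - j - 1) + pair[i2][j2],
                )

    for i in range(n):
        for j in range(L):
            rec(i, j, pair[i][j])
    return best


def naive_ward_linkage(dmat: np.ndarray):
    """Ward.D agglomeration recomputing the whole distance table at each merge.

    Returns a list of (id_left, id_right, height, size) mirroring the
    linkage convention, with index-order tie-breaking.
    """
    d = np.array(dmat, dtype=float)
    n = d.shape[0]
    clusters = {i: (i, 1) for i in range(n)}  # slot -> (node id, size)
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        slots = sorted(clusters)
        best = None
        for a in range(len(slots)):
            for b in range(a + 1, len(slots)):
                key = (slots[a], slots[b])
                if best is None or dist[key] < best[0] - 1e-15:
                    best = (dist[key], slots[a], slots[b])
        h, si, sj = best
        (idi, ni), (idj, nj) = clusters[si], clusters[sj]
        merges.append((idi, idj, h, ni + nj))
        new = {}
        for sk in slots:
            if sk in (si, sj):
                continue
            nk = clusters[sk][1]
            dik = dist[tuple(sorted((si, sk)))]
            djk = dist[tuple(sorted((sj, sk)))]
            new[sk] = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
        del clusters[sj]
        clusters[si] = (next_id, ni + nj)
        next_id += 1
        dist = {
            tuple(sorted((a, b))): (
                new[b] if si == a else new[a] if si == b else dist[tuple(sorted((a, b)))]
            )
            for a in clusters
            for b in clusters
            if a < b
        }
    return merges
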