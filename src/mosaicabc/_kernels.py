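"""Compiled inner loops for spatial placement and biopsy tallying.

The seed-and-grow placement is inherently sequential per embryo, so the
hot loops are jitted with numba.  All randomness enters through arrays of
uniform variates drawn from the caller's numpy Generator, keeping results
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def grow_clusters(neighbor_order, seeds, cluster_choices):
    """Mark aneuploid cells by growing clusters from seed cells.

    Each growth step picks the cluster named in ``cluster_choices`` and marks
    the nearest not-yet-marked cell in that cluster seed's neighbor ordering.
    Returns the ids of all marked cells (seeds first).
    """
    n_cells = neighbor_order.shape[0]
    s = seeds.shape[0]
    n_an = s + cluster_choices.shape[0]
    marked = np.zeros(n_cells, dtype=np.bool_)
    out = np.empty(n_an, dtype=np.int64)
    ptr = np.zeros(s, dtype=np.int64)
    for j in range(s):
        marked[seeds[j]] = True
        out[j] = seeds[j]
    m = s
    for t in range(cluster_choices.shape[0]):
        c = cluster_choices[t]
        row = neighbor_order[seeds[c]]
        k = ptr[c]
        while marked[row[k]]:
            k += 1
        marked[row[k]] = True
        out[m] = row[k]
        ptr[c] = k + 1
        m += 1
    return out


@njit(cache=False)
def biopsy_counts_batch(neighbor_order, biopsy_sets, n_an_arr, seed_counts, idx1, idx2, u):
    """Aneuploid counts of one or two biopsies for a batch of embryos.

    ``u`` holds one row of uniform variates per embryo: the first ``s``
    entries drive seed selection (partial Fisher-Yates), the next
    ``n_an - s`` entries drive cluster choices.  ``idx2[e] < 0`` skips the
    second biopsy.  Fully euploid / fully aneuploid embryos bypass placement.
    """
    n_embryos = n_an_arr.shape[0]
    n_cells = neighbor_order.shape[0]
    bsize = biopsy_sets.shape[1]
    counts1 = np.empty(n_embryos, dtype=np.int64)
    counts2 = np.full(n_embryos, -1, dtype=np.int64)

    stamp = np.zeros(n_cells, dtype=np.int64)  # "marked" flag versioned per embryo
    pool = np.empty(n_cells, dtype=np.int64)
    seeds = np.empty(n_cells, dtype=np.int64)
    ptr = np.empty(n_cells, dtype=np.int64)

    for e in range(n_embryos):
        n_an = n_an_arr[e]
        if n_an == 0 or n_an == n_cells:
            c = 0 if n_an == 0 else bsize
            counts1[e] = c
            if idx2[e] >= 0:
                counts2[e] = c
            continue
        cur = e + 1
        s = seed_counts[e]
        # seed selection: partial Fisher-Yates over cell ids
        for i in range(n_cells):
            pool[i] = i
        for j in range(s):
            k = j + int(u[e, j] * (n_cells - j))
            tmp = pool[j]
            pool[j] = pool[k]
            pool[k] = tmp
            seeds[j] = pool[j]
            stamp[pool[j]] = cur
            ptr[j] = 0
        # growth
        for t in range(n_an - s):
            c = int(u[e, s + t] * s)
            row = neighbor_order[seeds[c]]
            k = ptr[c]
            while stamp[row[k]] == cur:
                k += 1
            stamp[row[k]] = cur
            ptr[c] = k + 1
        # tally biopsies
        b = biopsy_sets[idx1[e]]
        cnt = 0
        for i in range(bsize):
            if stamp[b[i]] == cur:
                cnt += 1
        counts1[e] = cnt
        if idx2[e] >= 0:
            b2 = biopsy_sets[idx2[e]]
            cnt2 = 0
            for i in range(bsize):
                if stamp[b2[i]] == cur:
                    cnt2 += 1
            counts2[e] = cnt2
    return counts1, counts2
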