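"""Independent brute-force oracles used to cross-check the fast implementations.

Everything here is deliberately naive: all-pairs scans and explicit loops,
with no interval trees, no vectorized ranking shortcuts, no shared code
with the package internals beyond the public data types.
"""

from __future__ import annotations

import numpy as np


def brute_overlaps(a, b) -> bool:
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def brute_shared_peaks(r1, r2) -> list[int]:
    """Indices of r1 peaks having >= 1 bp overlap with any r2 peak (all pairs)."""
    shared = []
    for i, p in enumerate(r1):
        if any(brute_overlaps(p.interval, q.interval) for q in r2):
            shared.append(i)
    return shared


def brute_overlap_flags(peaks, regions) -> list[bool]:
    return [
        any(brute_overlaps(p.interval, iv) for iv in regions)
        for p in peaks
    ]


def brute_nearest_gene(chrom: str, point: int, genes, max_dist: int):
    """(gene_id, signed strand-aware distance) or (None, None), by full scan."""
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(point - g.tss)
        if best is None or d < best[1] or (d == best[1] and g.gene_id < best[0].gene_id):
            best = (g, d)
    if best is None or best[1] > max_dist:
        return None, None
    g = best[0]
    delta = point - g.tss
    return g.gene_id, (delta if g.strand == "+" else -delta)


def brute_rank_product(values: np.ndarray, n_control: int, direction: str) -> np.ndarray:
    """Exhaustive rank product: explicit loops over comparisons and probes."""
    n_probes, n_samples = values.shape
    control = values[:, :n_control]
    treated = values[:, n_control:]
    comparisons = []
    for i in range(treated.shape[1]):
        for j in range(control.shape[1]):
            comparisons.append(treated[:, i] - control[:, j])
    all_ranks = np.empty((n_probes, len(comparisons)))
    for k, fc in enumerate(comparisons):
        keyed = -fc if direction == "up" else fc
        # average ranks for ties, rank 1 = most changed in the direction
        order = np.argsort(keyed, kind="stable")
        ranks = np.empty(n_probes)
        pos = 0
        while pos < n_probes:
            end = pos
            while end + 1 < n_probes and keyed[order[end + 1]] == keyed[order[pos]]:
                end += 1
            avg = (pos + end) / 2 + 1
            for idx in order[pos : end + 1]:
                ranks[idx] = avg
            pos = end + 1
        all_ranks[:, k] = ranks
    return np.prod(all_ranks, axis=1) ** (1.0 / len(comparisons))
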