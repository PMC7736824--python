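"""Independent brute-force oracles for the interval operations.

Deliberately naive (explicit per-base arrays, quadratic linkage) so they
share no code path with the implementations they check."""

from __future__ import annotations

import numpy as np

LIMIT = 100_000


def brute_reproducible(replicates, min_support, limit=LIMIT):
    """Per-base support counting with explicit arrays."""
    chroms = {c for rep in replicates for c, _, _ in rep}
    out = []
    for chrom in sorted(chroms):
        depth = np.zeros(limit, dtype=int)
        for rep in replicates:
            covered = np.zeros(limit, dtype=bool)
            for c, s, e in rep:
                if c == chrom:
                    covered[s:e] = True
            depth += covered
        ok = depth >= min_support
        padded = np.diff(np.concatenate([[0], ok.view(np.int8), [0]]))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def brute_cluster(peaks, cluster_bp):
    """Quadratic single-linkage by repeated pairwise merging."""
    groups = [[p] for p in sorted(peaks)]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] and groups[j] and _linked(groups[i], groups[j], cluster_bp):
                    groups[i] += groups[j]
                    groups[j] = []
                    changed = True
        groups = [g for g in groups if g]
    zones = []
    for g in groups:
        chrom = g[0][0]
        zones.append((chrom, min(p[1] for p in g), max(p[2] for p in g), len(g)))
    return sorted(zones)


def _linked(ga, gb, cluster_bp):
    for ca, sa, ea in ga:
        for cb, sb, eb in gb:
            if ca == cb and max(sa, sb) - min(ea, eb) <= cluster_bp:
                return True
    return False


def random_instance(rng, n_reps=3, n_peaks=12, limit=LIMIT):
    reps = []
    for _ in range(n_reps):
        peaks = []
        for _ in range(rng.integers(0, n_peaks + 1)):
            start = int(rng.integers(0, limit - 2000))
            width = int(rng.integers(1, 2000))
            chrom = "chr" + str(rng.integers(1, 3))
            peaks.append((chrom, start, start + width))
        reps.append(sorted(peaks))
    return reps
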