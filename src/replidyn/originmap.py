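"""Genome-wide origin interval analysis.

Operates on BED-style origin peak sets (0-based, half-open): replicate
reproducibility filtering with per-base multi-intersection semantics,
single-linkage clustering of initiation sites into initiation zones at a
chosen resolution (22 kb matches the mapping resolution of Okazaki-fragment
sequencing), midpoint-to-midpoint inter-origin distances with gap-spanning
distances omitted, and per-chromosome summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

Interval = tuple[str, int, int]

__all__ = [
    "InitiationZone",
    "IODDistribution",
    "merge_intervals",
    "reproducible_peaks",
    "cluster_initiation_sites",
    "iod_from_zones",
    "per_chromosome_summary",
]


@dataclass
class InitiationZone:
    chrom: str
    start: int
    end: int
    n_member_peaks: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class IODDistribution:
    """Midpoint-to-midpoint distances (bp) between adjacent zones."""

    per_chromosome: dict[str, list[int]]
    n_omitted_gap_spanning: int = 0

    def all_distances(self) -> list[int]:
        return [d for ds in self.per_chromosome.values() for d in ds]

    @property
    def mean(self) -> float:
        d = self.all_distances()
        return float(np.mean(d)) if d else float("nan")

    @property
    def median(self) -> float:
        d = self.all_distances()
        return float(np.median(d)) if d else float("nan")


def _validate_chrom_naming(sets: Sequence[Iterable[Interval]]) -> None:
    # mixed "chr1"/"1" style input silently breaks per-chromosome grouping
    seen_prefixed = seen_bare = False
    for s in sets:
        for chrom, _, _ in s:
            if chrom.startswith("chr"):
                seen_prefixed = True
            else:
                seen_bare = True
    if seen_prefixed and seen_bare:
        raise ValueError("mixed chromosome naming (chr-prefixed and bare)")


def _check_intervals(peaks: Iterable[Interval]) -> list[Interval]:
    out = []
    for chrom, start, end in peaks:
        if start < 0 or end < start:
            raise ValueError(f"malformed interval {(chrom, start, end)}")
        if end > start:
            out.append((chrom, int(start), int(end)))
    return sorted(out)


def merge_intervals(peaks: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as maximal non-overlapping runs (touching
    intervals merge)."""
    merged: list[list] = []
    for chrom, start, end in _check_intervals(peaks):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def reproducible_peaks(
    replicates: Sequence[Iterable[Interval]],
    min_support: int = 2,
    method: str = "basewise",
) -> list[Interval]:
    """Genomic regions supported by at least ``min_support`` replicates.

    ``basewise`` (default) counts, per base, the number of distinct
    replicates covering it and emits maximal runs with support ≥
    min_support — the multi-intersection reading of "peaks reproducibly
    found in at least two replicates".  ``peakwise`` instead keeps every
    pooled peak overlapped by peaks from ≥ min_support distinct replicates
    and merges the survivors.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(replicates) < min_support:
        raise ValueError(
            f"need at least min_support={min_support} replicate sets, "
            f"got {len(replicates)}"
        )
    _validate_chrom_naming(replicates)
    merged_reps = [merge_intervals(r) for r in replicates]
    if method == "basewise":
        return _basewise_support(merged_reps, min_support)
    if method == "peakwise":
        return _peakwise_support(replicates, merged_reps, min_support)
    raise ValueError(f"unknown method {method!r}")


def _basewise_support(
    merged_reps: Sequence[list[Interval]], min_support: int
) -> list[Interval]:
    # boundary sweep: +1 at starts, -1 at ends, per chromosome
    events: dict[str, dict[int, int]] = {}
    for rep in merged_reps:
        for chrom, start, end in rep:
            ch = events.setdefault(chrom, {})
            ch[start] = ch.get(start, 0) + 1
            ch[end] = ch.get(end, 0) - 1
    out: list[Interval] = []
    for chrom in sorted(events):
        depth = 0
        run_start: Optional[int] = None
        for pos in sorted(events[chrom]):
            depth += events[chrom][pos]
            if depth >= min_support and run_start is None:
                run_start = pos
            elif depth < min_support and run_start is not None:
                out.append((chrom, run_start, pos))
                run_start = None
    return out


def _peakwise_support(
    replicates: Sequence[Iterable[Interval]],
    merged_reps: Sequence[list[Interval]],
    min_support: int,
) -> list[Interval]:
    pooled = _check_intervals(p for rep in replicates for p in rep)
    kept = []
    for peak in pooled:
        support = sum(1 for rep in merged_reps if _overlaps_any(peak, rep))
        if support >= min_support:
            kept.append(peak)
    return merge_intervals(kept)


def _overlaps_any(peak: Interval, sorted_rep: list[Interval]) -> bool:
    chrom, start, end = peak
    for c, s, e in sorted_rep:
        if c != chrom:
            continue
        if s >= end:
            break
        if e > start:
            return True
    return False


def cluster_initiation_sites(
    peaks: Iterable[Interval], cluster_bp: int = 22_000
) -> list[InitiationZone]:
    """Single-linkage merge of peaks into initiation zones.

    Consecutive peaks whose edge-to-edge gap is at most ``cluster_bp`` join
    one zone; the zone spans its member peaks.  ``cluster_bp`` 0 merges only
    touching peaks.
    """
    if cluster_bp < 0:
        raise ValueError("cluster_bp must be non-negative")
    zones: list[InitiationZone] = []
    for chrom, start, end in _check_intervals(peaks):
        z = zones[-1] if zones else None
        if z is not None and z.chrom == chrom and start - z.end <= cluster_bp:
            z.end = max(z.end, end)
            z.n_member_peaks += 1
        else:
            zones.append(InitiationZone(chrom, start, end, 1))
    return zones


def iod_from_zones(
    zones: Sequence[InitiationZone],
    gaps: Optional[Iterable[Interval]] = None,
    max_distance_bp: Optional[int] = 1_000_000,
) -> IODDistribution:
    """Midpoint-to-midpoint distances between adjacent zones per chromosome.

    A distance is omitted (and counted) when its span intersects a declared
    gap interval (unmappable regions: centromeres, etc.) or, when no gap set
    is supplied, when it exceeds ``max_distance_bp`` (an implicit-gap
    ceiling; pass None to disable).
    """
    gap_list = merge_intervals(gaps) if gaps is not None else None
    by_chrom: dict[str, list[InitiationZone]] = {}
    for z in zones:
        by_chrom.setdefault(z.chrom, []).append(z)
    per_chrom: dict[str, list[int]] = {}
    omitted = 0
    for chrom, zs in by_chrom.items():
        zs = sorted(zs, key=lambda z: (z.start, z.end))
        dists = []
        for a, b in zip(zs, zs[1:]):
            d = b.midpoint - a.midpoint
            if d <= 0:
                continue
            span = (chrom, a.midpoint, b.midpoint)
            if gap_list is not None:
                if _overlaps_any(span, gap_list):
                    omitted += 1
                    continue
            elif max_distance_bp is not None and d > max_distance_bp:
                omitted += 1
                continue
            dists.append(int(d))
        per_chrom[chrom] = dists
    return IODDistribution(per_chrom, n_omitted_gap_spanning=omitted)


_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def per_chromosome_summary(dist: IODDistribution, flag_fold: float = 2.0) -> pd.DataFrame:
    """Per-chromosome IOD mean/median/count with outlier flags.

    A chromosome is flagged when its mean IOD differs from the mean over
    autosomes by at least ``flag_fold``-fold in either direction (e.g. the
    X chromosome showing twice the autosomal spacing).  Chromosomes with
    fewer than two zones (no distances) are reported as NA."""
    rows = []
    autosomal = [
        d
        for chrom, ds in dist.per_chromosome.items()
        if chrom not in _SEX_CHROMS
        for d in ds
    ]
    auto_mean = float(np.mean(autosomal)) if autosomal else float("nan")
    for chrom in sorted(dist.per_chromosome):
        ds = dist.per_chromosome[chrom]
        if not ds:
            rows.append(
                {
                    "chrom": chrom,
                    "n": 0,
                    "mean_bp": float("nan"),
                    "median_bp": float("nan"),
                    "flagged": False,
                }
            )
            continue
        mean = float(np.mean(ds))
        flagged = bool(
            np.isfinite(auto_mean)
            and auto_mean > 0
            and (mean >= flag_fold * auto_mean or mean <= auto_mean / flag_fold)
        )
        rows.append(
            {
                "chrom": chrom,
                "n": len(ds),
                "mean_bp": mean,
                "median_bp": float(np.median(ds)),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "n", "mean_bp", "median_bp", "flagged"])
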