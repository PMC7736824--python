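"""Multi-replicate origin-peak simulator.

Emulates the structure of short-nascent-strand (SNS-seq) peak sets: true
initiation zones laid down at truncated-normal spacing along each
chromosome, each contributing a small cluster of fixed-width peaks
(alternative initiation sites), with each peak detected independently per
replicate.  Declared unmappable gaps (centromeres etc.) carry no zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .._sampling import check_truncation_mass, truncated_normal

Interval = tuple[str, int, int]


@dataclass
class OriginSimConfig:
    chrom_sizes: Mapping[str, int]
    n_replicates: int = 2
    zone_spacing_mean_bp: float = 70_000.0
    zone_spacing_sd_bp: float = 10_000.0
    sites_per_zone_mean: float = 2.0
    peak_width_bp: int = 500
    replicate_detection_prob: float = 0.9
    gap_intervals: Sequence[Interval] = field(default_factory=tuple)
    zone_extent_bp: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        if any(size <= 0 for size in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.peak_width_bp <= 0:
            raise ValueError("peak_width_bp must be positive")
        if self.zone_spacing_mean_bp < self.peak_width_bp:
            raise ValueError("zone spacing smaller than peak width")
        if self.sites_per_zone_mean < 1:
            raise ValueError("sites_per_zone_mean must be >= 1")
        if not 0.0 <= self.replicate_detection_prob <= 1.0:
            raise ValueError("replicate_detection_prob must lie in [0, 1]")
        check_truncation_mass(
            self.zone_spacing_mean_bp, self.zone_spacing_sd_bp, "zone spacing"
        )
        for chrom, start, end in self.gap_intervals:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"gap on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chrom_sizes[chrom]:
                raise ValueError("malformed gap interval")


def simulate_origin_maps(
    cfg: OriginSimConfig,
) -> tuple[dict[int, list[Interval]], pd.DataFrame]:
    """Simulate per-replicate peak sets.

    Returns (replicates, zones) where ``replicates`` maps replicate id (0-based)
    to a sorted list of BED-style (chrom, start, end) peaks and ``zones`` is the
    ground-truth table with one row per true zone (zone_id, chrom, start, end,
    center_bp, n_sites).
    """
    rng = np.random.default_rng(cfg.seed)
    half_extent = cfg.zone_extent_bp // 2
    replicates: dict[int, list[Interval]] = {r: [] for r in range(cfg.n_replicates)}
    zone_rows: list[dict] = []
    zone_id = 0
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        gaps = sorted(
            (s, e) for c, s, e in cfg.gap_intervals if c == chrom
        )
        pos = float(rng.uniform(0, cfg.zone_spacing_mean_bp))
        while pos < size:
            center = int(pos)
            lo = center - half_extent - cfg.peak_width_bp
            hi = center + half_extent + cfg.peak_width_bp
            in_gap = next(((s, e) for s, e in gaps if lo < e and s < hi), None)
            if in_gap is not None:
                # zones may not touch unmappable regions: jump past the gap
                pos = in_gap[1] + half_extent + cfg.peak_width_bp + 1.0
                continue
            if lo < 0 or hi > size:
                pos += float(
                    truncated_normal(
                        rng, cfg.zone_spacing_mean_bp, cfg.zone_spacing_sd_bp, 1
                    )[0]
                )
                continue
            n_sites = 1 + int(rng.poisson(cfg.sites_per_zone_mean - 1.0))
            site_centers = np.sort(
                rng.uniform(center - half_extent, center + half_extent, n_sites)
            )
            for sc in site_centers:
                start = int(round(sc - cfg.peak_width_bp / 2))
                peak = (chrom, start, start + cfg.peak_width_bp)
                for r in range(cfg.n_replicates):
                    if rng.random() < cfg.replicate_detection_prob:
                        replicates[r].append(peak)
            zone_rows.append(
                {
                    "zone_id": zone_id,
                    "chrom": chrom,
                    "start": int(site_centers[0] - cfg.peak_width_bp / 2),
                    "end": int(site_centers[-1] + cfg.peak_width_bp / 2),
                    "center_bp": center,
                    "n_sites": n_sites,
                }
            )
            zone_id += 1
            pos += float(
                truncated_normal(
                    rng, cfg.zone_spacing_mean_bp, cfg.zone_spacing_sd_bp, 1
                )[0]
            )
    for r in replicates:
        replicates[r].sort()
    zones = pd.DataFrame(zone_rows)
    return replicates, zones
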