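"""Readers/writers for the package's exchange formats.

Fibers: tab-separated table (fiber_id, segment_label, start_um, end_um) with
one ssDNA row per fiber giving its extent.  Origins: BED3 (replicate id
lives in the filename).  Images: one multi-page TIFF per channel plus a JSON
sidecar holding the voxel size.  Growth curves: CSV (time_h, count).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .fiberkit import SSDNA, FiberTrack, Segment
from .focikit import VoxelGrid
from .originmap import Interval
from .synthgen.growth import GrowthCurve

FIBER_COLUMNS = ["fiber_id", "segment_label", "start_um", "end_um"]


def write_fibers(fibers: Iterable[FiberTrack], path: str | Path) -> None:
    # floats written with repr so coordinates round-trip exactly
    with open(path, "w") as fh:
        fh.write("\t".join(FIBER_COLUMNS) + "\n")
        for f in fibers:
            fh.write(f"{f.fiber_id}\t{SSDNA}\t{f.ssdna_extent[0]!r}\t{f.ssdna_extent[1]!r}\n")
            for s in f.segments:
                fh.write(f"{f.fiber_id}\t{s.label}\t{s.start_um!r}\t{s.end_um!r}\n")


def read_fibers(path: str | Path) -> list[FiberTrack]:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(FIBER_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"fiber table missing columns {sorted(missing)}")
    fibers = []
    for fiber_id, group in table.groupby("fiber_id", sort=False):
        ss = group[group.segment_label == SSDNA]
        if len(ss) != 1:
            raise ValueError(f"fiber {fiber_id}: expected exactly one ssDNA row")
        extent = (float(ss.start_um.iloc[0]), float(ss.end_um.iloc[0]))
        segs = [
            Segment(r.segment_label, float(r.start_um), float(r.end_um))
            for r in group.itertuples()
            if r.segment_label != SSDNA
        ]
        fibers.append(FiberTrack(str(fiber_id), segs, extent))
    return fibers


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path, one_based: bool = False) -> list[Interval]:
    """Read BED3 (0-based, half-open).  Declared 1-based inclusive input is
    converted on read."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            start, end = int(start), int(end)
            if one_based:
                start -= 1
            out.append((chrom, start, end))
    return out


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Multi-page TIFF plus a JSON voxel-size sidecar (<path>.json)."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(grid.data, dtype=np.float32), photometric="minisblack"
    )
    sidecar = {"voxel_nm_zyx": list(grid.voxel_nm), "channel_name": grid.channel_name}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_stack(path: str | Path) -> VoxelGrid:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return VoxelGrid(
        data, tuple(sidecar["voxel_nm_zyx"]), sidecar.get("channel_name", "")
    )


def write_growth(curve: GrowthCurve, path: str | Path) -> None:
    pd.DataFrame({"time_h": curve.times_h, "count": curve.counts}).to_csv(
        path, index=False
    )


def read_growth(path: str | Path) -> GrowthCurve:
    table = pd.read_csv(path)
    return GrowthCurve(list(table["time_h"]), list(table["count"]))
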