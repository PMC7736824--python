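"""Molecular-combing fiber analysis.

Measures replication dynamics from single stretched DNA molecules carrying
dual-pulse nucleotide labels (IdU first pulse, CldU second pulse).  On combed
fibers 1 μm corresponds to a constant number of kilobases (the stretching
factor, 2 kb/μm), so track lengths convert directly to nucleotides and, with
the pulse duration, to fork speed.

Track grammar
-------------
A progressing fork reads, in the direction of travel, IdU then CldU
(contiguous).  A bidirectional origin is two forks diverging from a shared
IdU-internal junction: the spatial pattern CldU–IdU–IdU–CldU, with the origin
at the IdU–IdU junction.  A lone fork whose IdU (origin-side) edge abuts
unlabeled ssDNA, with no other labeled track within an exclusion distance, is
scored as a unidirectional origin.  Forks are only used for speed measurement
when ssDNA is visible beyond both ends of the structure — this excludes
tracks cut by the fiber end and tracks that merged with a converging
neighbor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Segment",
    "FiberTrack",
    "ForkMeasurement",
    "OriginCall",
    "CombingSummary",
    "classify_tracks",
    "call_origins",
    "fork_speed",
    "inter_origin_distances",
    "fork_asymmetry",
    "unidirectional_fraction",
    "summarize_combing",
]

SSDNA = "ssDNA"
IDU = "IdU"
CLDU = "CldU"

#: positional tolerance (μm) below which two segment edges count as abutting
CONTIG_TOL_UM = 1e-6


@dataclass(frozen=True)
class Segment:
    label: str
    start_um: float
    end_um: float

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um

    @property
    def mid_um(self) -> float:
        return 0.5 * (self.start_um + self.end_um)


@dataclass
class FiberTrack:
    """One combed DNA molecule: labeled segments plus its ssDNA extent."""

    fiber_id: str
    segments: list[Segment]
    ssdna_extent: tuple[float, float]

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.start_um, s.end_um))
        lo, hi = self.ssdna_extent
        if not hi > lo:
            raise ValueError(f"fiber {self.fiber_id}: empty ssDNA extent")
        for seg in self.segments:
            if seg.label not in (IDU, CLDU):
                raise ValueError(f"fiber {self.fiber_id}: unknown label {seg.label!r}")
            if seg.length_um <= 0:
                raise ValueError(f"fiber {self.fiber_id}: non-positive segment")
            if seg.start_um < lo - CONTIG_TOL_UM or seg.end_um > hi + CONTIG_TOL_UM:
                raise ValueError(
                    f"fiber {self.fiber_id}: labeled segment outside ssDNA extent"
                )
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_um < a.end_um - CONTIG_TOL_UM:
                raise ValueError(f"fiber {self.fiber_id}: overlapping segments")


@dataclass
class ForkMeasurement:
    fiber_id: str
    structure_id: str
    direction: str  # "left" | "right"
    idu_length_um: float
    cldu_length_um: float
    origin_id: Optional[str] = None  # shared by sibling forks of one origin
    origin_pos_um: Optional[float] = None
    unidirectional: bool = False
    valid: bool = True
    invalid_reason: Optional[str] = None


@dataclass
class OriginCall:
    """A fork structure: a bidirectional origin or a unidirectional fork.

    ``kind`` is "bidirectional", "unidirectional" or "ambiguous" (a lone fork
    with another labeled track too close to its origin-side edge to rule out
    a broken partner)."""

    fiber_id: str
    origin_id: str
    position_um: float
    kind: str
    forks: list[ForkMeasurement] = field(default_factory=list)


@dataclass
class CombingSummary:
    rfs_mean: float
    rfs_sem: Optional[float]
    iod_mean: Optional[float]
    iod_sem: Optional[float]
    pct_unidirectional: Optional[float]
    asymmetry_ratios: list[float]
    n_forks: int
    n_origins: int
    n_asymmetry_excluded: int = 0


def _sem(values: Sequence[float]) -> Optional[float]:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def _contig(a: Segment, b: Segment) -> bool:
    return abs(b.start_um - a.end_um) <= CONTIG_TOL_UM


def classify_tracks(
    fibers: Iterable[FiberTrack], exclusion_um: float = 5.0
) -> list[ForkMeasurement]:
    """Parse labeled segments into fork measurements.

    Walks each fiber left to right consuming the track grammar described in
    the module docstring.  A fork is marked invalid (excluded from speed
    statistics) when ssDNA is not visible beyond its CldU end or, for a lone
    fork, beyond its IdU end; unparseable or orphan segments are marked
    invalid with a reason.
    """
    forks: list[ForkMeasurement] = []
    for fiber in fibers:
        forks.extend(_classify_fiber(fiber, exclusion_um))
    return forks


def _classify_fiber(fiber: FiberTrack, exclusion_um: float) -> list[ForkMeasurement]:
    segs = fiber.segments
    out: list[ForkMeasurement] = []
    n = len(segs)
    i = 0
    struct_idx = 0

    def new_ids() -> tuple[str, str]:
        nonlocal struct_idx
        sid = f"{fiber.fiber_id}:s{struct_idx}"
        struct_idx += 1
        return sid, sid

    while i < n:
        s = segs[i]
        # bidirectional origin: CldU IdU IdU CldU, all contiguous
        if (
            s.label == CLDU
            and i + 3 < n
            and segs[i + 1].label == IDU
            and segs[i + 2].label == IDU
            and segs[i + 3].label == CLDU
            and _contig(s, segs[i + 1])
            and _contig(segs[i + 1], segs[i + 2])
            and _contig(segs[i + 2], segs[i + 3])
        ):
            sid, oid = new_ids()
            pos = segs[i + 1].end_um
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "left", segs[i + 1].length_um, s.length_um,
                    origin_id=oid, origin_pos_um=pos,
                )
            )
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "right",
                    segs[i + 2].length_um, segs[i + 3].length_um,
                    origin_id=oid, origin_pos_um=pos,
                )
            )
            _flank_check(out[-2], fiber, segs, i, i + 3)
            _flank_check(out[-1], fiber, segs, i, i + 3)
            i += 4
            continue
        # origin whose right fork lost its CldU to a termination event:
        # CldU IdU IdU (no contiguous CldU after)
        if (
            s.label == CLDU
            and i + 2 < n
            and segs[i + 1].label == IDU
            and segs[i + 2].label == IDU
            and _contig(s, segs[i + 1])
            and _contig(segs[i + 1], segs[i + 2])
            and not (
                i + 3 < n
                and segs[i + 3].label == CLDU
                and _contig(segs[i + 2], segs[i + 3])
            )
        ):
            sid, oid = new_ids()
            pos = segs[i + 1].end_um
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "left", segs[i + 1].length_um, s.length_um,
                    origin_id=oid, origin_pos_um=pos,
                )
            )
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "right", segs[i + 2].length_um, 0.0,
                    origin_id=oid, origin_pos_um=pos,
                    valid=False, invalid_reason="no flanking ssDNA",
                )
            )
            _flank_check(out[-2], fiber, segs, i, i + 2)
            i += 3
            continue
        # mirror image: IdU IdU CldU — the left fork lost its CldU
        if (
            s.label == IDU
            and i + 2 < n
            and segs[i + 1].label == IDU
            and segs[i + 2].label == CLDU
            and _contig(s, segs[i + 1])
            and _contig(segs[i + 1], segs[i + 2])
        ):
            sid, oid = new_ids()
            pos = s.end_um
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "left", s.length_um, 0.0,
                    origin_id=oid, origin_pos_um=pos,
                    valid=False, invalid_reason="no flanking ssDNA",
                )
            )
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "right",
                    segs[i + 1].length_um, segs[i + 2].length_um,
                    origin_id=oid, origin_pos_um=pos,
                )
            )
            _flank_check(out[-1], fiber, segs, i, i + 2)
            i += 3
            continue
        # bidirectional origin with a single merged IdU: CldU IdU CldU
        if (
            s.label == CLDU
            and i + 2 < n
            and segs[i + 1].label == IDU
            and segs[i + 2].label == CLDU
            and _contig(s, segs[i + 1])
            and _contig(segs[i + 1], segs[i + 2])
        ):
            sid, oid = new_ids()
            half = 0.5 * segs[i + 1].length_um
            pos = segs[i + 1].mid_um
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "left", half, s.length_um,
                    origin_id=oid, origin_pos_um=pos,
                )
            )
            out.append(
                ForkMeasurement(
                    fiber.fiber_id, sid, "right", half, segs[i + 2].length_um,
                    origin_id=oid, origin_pos_um=pos,
                )
            )
            _flank_check(out[-2], fiber, segs, i, i + 2)
            _flank_check(out[-1], fiber, segs, i, i + 2)
            i += 2 + 1
            continue
        # leftward lone fork: CldU IdU
        if (
            s.label == CLDU
            and i + 1 < n
            and segs[i + 1].label == IDU
            and _contig(s, segs[i + 1])
        ):
            sid, _ = new_ids()
            fm = ForkMeasurement(
                fiber.fiber_id, sid, "left", segs[i + 1].length_um, s.length_um,
                origin_pos_um=segs[i + 1].end_um,
            )
            _flank_check(fm, fiber, segs, i, i + 1)
            _score_unidirectional(fm, fiber, segs, i, i + 1, exclusion_um)
            out.append(fm)
            i += 2
            continue
        # rightward lone fork: IdU CldU
        if (
            s.label == IDU
            and i + 1 < n
            and segs[i + 1].label == CLDU
            and _contig(s, segs[i + 1])
        ):
            sid, _ = new_ids()
            fm = ForkMeasurement(
                fiber.fiber_id, sid, "right", s.length_um, segs[i + 1].length_um,
                origin_pos_um=s.start_um,
            )
            _flank_check(fm, fiber, segs, i, i + 1)
            _score_unidirectional(fm, fiber, segs, i, i + 1, exclusion_um)
            out.append(fm)
            i += 2
            continue
        # orphan segment — no parseable fork
        sid, _ = new_ids()
        out.append(
            ForkMeasurement(
                fiber.fiber_id, sid,
                "right" if s.label == CLDU else "left",
                s.length_um if s.label == IDU else 0.0,
                s.length_um if s.label == CLDU else 0.0,
                valid=False, invalid_reason="orphan segment",
            )
        )
        i += 1
    return out


def _flank_check(
    fm: ForkMeasurement, fiber: FiberTrack, segs: list[Segment], lo: int, hi: int
) -> None:
    """Require visible ssDNA beyond both outer ends of the structure.

    ``lo``/``hi`` index the outermost segments of the structure the fork
    belongs to.  A structure edge that coincides with the ssDNA extent end
    (fiber break) or abuts a neighboring labeled track fails the check."""
    left_edge = segs[lo].start_um
    right_edge = segs[hi].end_um
    ss_lo, ss_hi = fiber.ssdna_extent
    ok_left = left_edge > ss_lo + CONTIG_TOL_UM and (
        lo == 0 or segs[lo - 1].end_um < left_edge - CONTIG_TOL_UM
    )
    ok_right = right_edge < ss_hi - CONTIG_TOL_UM and (
        hi == len(segs) - 1 or segs[hi + 1].start_um > right_edge + CONTIG_TOL_UM
    )
    # the relevant end for speed is the fork's own CldU (distal) end, but the
    # selection rule asks for ssDNA up- AND downstream of the marked tracks
    if not (ok_left and ok_right):
        fm.valid = False
        fm.invalid_reason = "no flanking ssDNA"


def _score_unidirectional(
    fm: ForkMeasurement,
    fiber: FiberTrack,
    segs: list[Segment],
    lo: int,
    hi: int,
    exclusion_um: float,
) -> None:
    """Lone fork: unidirectional only if nothing labeled sits within the
    exclusion distance of its IdU (origin-side) edge.  Forks already excluded
    by the flanking-ssDNA rule stay unscored (kind "ambiguous")."""
    if not fm.valid:
        return
    if fm.direction == "right":
        edge = segs[lo].start_um
        neighbor = segs[lo - 1].end_um if lo > 0 else None
        clear = neighbor is None or edge - neighbor > exclusion_um
    else:
        edge = segs[hi].end_um
        neighbor = segs[hi + 1].start_um if hi < len(segs) - 1 else None
        clear = neighbor is None or neighbor - edge > exclusion_um
    fm.unidirectional = bool(clear)


def call_origins(forks: Iterable[ForkMeasurement]) -> list[OriginCall]:
    """Group fork measurements into fork structures (origin calls)."""
    by_struct: dict[str, list[ForkMeasurement]] = {}
    order: list[str] = []
    for fm in forks:
        if fm.invalid_reason == "orphan segment":
            continue
        if fm.structure_id not in by_struct:
            order.append(fm.structure_id)
        by_struct.setdefault(fm.structure_id, []).append(fm)
    calls = []
    for sid in order:
        members = by_struct[sid]
        if len(members) == 2:
            kind = "bidirectional"
        elif members[0].unidirectional:
            kind = "unidirectional"
        else:
            kind = "ambiguous"
        calls.append(
            OriginCall(
                fiber_id=members[0].fiber_id,
                origin_id=sid,
                position_um=members[0].origin_pos_um,
                kind=kind,
                forks=members,
            )
        )
    return calls


def fork_speed(
    fork: ForkMeasurement, pulse_min: float, stretch_kb_per_um: float = 2.0
) -> float:
    """Fork speed in kb/min: second-pulse (CldU) track length × stretching
    factor / pulse duration."""
    if pulse_min <= 0:
        raise ValueError("pulse_min must be positive")
    if not fork.valid:
        raise ValueError(
            f"fork {fork.structure_id} is not a valid progressing fork "
            f"({fork.invalid_reason})"
        )
    return fork.cldu_length_um * stretch_kb_per_um / pulse_min


def inter_origin_distances(
    origins: Iterable[OriginCall], stretch_kb_per_um: float = 2.0
) -> list[float]:
    """Distances (kb) between adjacent origin midpoints on the same fiber.

    Uses bidirectional and unidirectional origin calls (both mark an
    initiation event); ambiguous lone forks are skipped."""
    by_fiber: dict[str, list[float]] = {}
    for oc in origins:
        if oc.kind in ("bidirectional", "unidirectional"):
            by_fiber.setdefault(oc.fiber_id, []).append(oc.position_um)
    dists = []
    for positions in by_fiber.values():
        positions.sort()
        dists.extend(
            (b - a) * stretch_kb_per_um for a, b in zip(positions, positions[1:])
        )
    if not dists:
        warnings.warn("no fiber carries two or more origins; IOD list is empty")
    return dists


def fork_asymmetry(
    origins: Iterable[OriginCall],
) -> tuple[list[float], int]:
    """Per-origin long/short CldU track ratio (≥ 1) for bidirectional origins
    with two valid sibling forks.  Returns (ratios, n_excluded) where
    n_excluded counts pairs whose short track is zero-length (undefined)."""
    ratios: list[float] = []
    excluded = 0
    for oc in origins:
        if oc.kind != "bidirectional":
            continue
        if not all(f.valid for f in oc.forks):
            continue
        a, b = sorted(f.cldu_length_um for f in oc.forks)
        if a <= 0:
            excluded += 1
            continue
        ratios.append(b / a)
    return ratios, excluded


def unidirectional_fraction(origins: Iterable[OriginCall]) -> float:
    """Percentage of unidirectional structures among analyzed fork structures
    (uni- plus bidirectional; a bidirectional origin counts once)."""
    n_uni = n_bi = 0
    for oc in origins:
        if oc.kind == "unidirectional":
            n_uni += 1
        elif oc.kind == "bidirectional":
            n_bi += 1
    total = n_uni + n_bi
    if total == 0:
        raise ValueError("no analyzed fork structures")
    return 100.0 * n_uni / total


def summarize_combing(
    forks: Sequence[ForkMeasurement],
    origins: Sequence[OriginCall],
    pulse_min: float,
    stretch_kb_per_um: float = 2.0,
) -> CombingSummary:
    """Aggregate fork/origin measurements into population statistics.

    SEM is sd/√n (sample sd); reported absent for n < 2."""
    speeds = [
        fork_speed(f, pulse_min, stretch_kb_per_um) for f in forks if f.valid
    ]
    iods = inter_origin_distances(origins, stretch_kb_per_um) if origins else []
    ratios, n_excl = fork_asymmetry(origins)
    try:
        pct_uni = unidirectional_fraction(origins)
    except ValueError:
        pct_uni = None
    return CombingSummary(
        rfs_mean=float(np.mean(speeds)) if speeds else float("nan"),
        rfs_sem=_sem(speeds),
        iod_mean=float(np.mean(iods)) if iods else None,
        iod_sem=_sem(iods),
        pct_unidirectional=pct_uni,
        asymmetry_ratios=ratios,
        n_forks=len(speeds),
        n_origins=sum(1 for o in origins if o.kind == "bidirectional"),
        n_asymmetry_excluded=n_excl,
    )
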