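"""Dual-pulse combing fiber simulator.

Fires origins along stretched DNA molecules at truncated-normal spacing and
elongates each non-stalled fork at a truncated-normal speed through both
labeling pulses (IdU then CldU), writing the resulting label segments in μm
at a fixed stretching factor.  Converging forks from adjacent origins
terminate where they meet (segments are truncated at the midpoint of the
would-be overlap), which preserves origin midpoints.  Ground truth — true
per-fork speeds, origin positions, directionality and truncation flags — is
returned as a sidecar table for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .._sampling import check_truncation_mass, truncated_normal
from ..fiberkit import CLDU, IDU, FiberTrack, Segment


@dataclass
class FiberSimConfig:
    n_fibers: int = 200
    pulse1_min: float = 15.0
    pulse2_min: float = 15.0
    stretch_kb_per_um: float = 2.0
    speed_mean_kb_min: float = 1.67
    speed_sd: float = 0.27
    iod_mean_kb: float = 90.0
    iod_sd_kb: float = 16.0
    p_fork_stall: float = 0.0
    fiber_len_mean_um: float = 250.0
    fiber_len_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers <= 0:
            raise ValueError("n_fibers must be positive")
        for name in (
            "pulse1_min",
            "pulse2_min",
            "stretch_kb_per_um",
            "speed_mean_kb_min",
            "iod_mean_kb",
            "fiber_len_mean_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.p_fork_stall <= 1.0:
            raise ValueError("p_fork_stall must lie in [0, 1]")
        check_truncation_mass(self.speed_mean_kb_min, self.speed_sd, "fork speed")
        check_truncation_mass(self.iod_mean_kb, self.iod_sd_kb, "inter-origin spacing")
        check_truncation_mass(
            self.fiber_len_mean_um, self.fiber_len_sd, "fiber length"
        )


@dataclass
class _Fork:
    fiber_id: str
    origin_id: str
    direction: str
    speed_kb_min: float
    origin_pos_um: float
    stalled: bool
    idu: Optional[list[float]] = None  # [start, end] μm, mutable for truncation
    cldu: Optional[list[float]] = None
    truncated: bool = False


def simulate_fibers(
    cfg: FiberSimConfig,
) -> tuple[list[FiberTrack], pd.DataFrame]:
    """Simulate combed fibers; returns (fibers, ground_truth).

    Ground truth has one row per fork (stalled forks included) with columns
    fiber_id, origin_id, direction, stalled, true_speed_kb_min,
    origin_pos_um, truncated, n_sibling_tracks.
    """
    rng = np.random.default_rng(cfg.seed)
    stretch = cfg.stretch_kb_per_um
    iod_um_mean = cfg.iod_mean_kb / stretch
    iod_um_sd = cfg.iod_sd_kb / stretch

    fibers: list[FiberTrack] = []
    gt_rows: list[dict] = []
    for fi in range(cfg.n_fibers):
        fiber_id = f"fiber{fi:05d}"
        length = float(truncated_normal(rng, cfg.fiber_len_mean_um, cfg.fiber_len_sd, 1)[0])
        positions: list[float] = []
        pos = float(rng.uniform(0.0, iod_um_mean))
        while pos < length:
            positions.append(pos)
            pos += float(truncated_normal(rng, iod_um_mean, iod_um_sd, 1)[0])

        forks: list[_Fork] = []
        for oi, opos in enumerate(positions):
            origin_id = f"{fiber_id}:o{oi}"
            for direction in ("left", "right"):
                stalled = bool(rng.random() < cfg.p_fork_stall)
                speed = float(
                    truncated_normal(rng, cfg.speed_mean_kb_min, cfg.speed_sd, 1)[0]
                )
                fork = _Fork(fiber_id, origin_id, direction, speed, opos, stalled)
                if not stalled:
                    idu_um = speed * cfg.pulse1_min / stretch
                    cldu_um = speed * cfg.pulse2_min / stretch
                    if direction == "right":
                        fork.idu = [opos, opos + idu_um]
                        fork.cldu = [opos + idu_um, opos + idu_um + cldu_um]
                    else:
                        fork.idu = [opos - idu_um, opos]
                        fork.cldu = [opos - idu_um - cldu_um, opos - idu_um]
                forks.append(fork)

        _resolve_collisions(forks, length)

        segments: list[Segment] = []
        tracks_per_origin: dict[str, int] = {}
        for fork in forks:
            has_track = fork.idu is not None and fork.idu[1] > fork.idu[0]
            tracks_per_origin[fork.origin_id] = tracks_per_origin.get(
                fork.origin_id, 0
            ) + (1 if has_track else 0)
            if not has_track:
                continue
            segments.append(Segment(IDU, fork.idu[0], fork.idu[1]))
            if fork.cldu is not None and fork.cldu[1] > fork.cldu[0]:
                segments.append(Segment(CLDU, fork.cldu[0], fork.cldu[1]))
        for fork in forks:
            gt_rows.append(
                {
                    "fiber_id": fork.fiber_id,
                    "origin_id": fork.origin_id,
                    "direction": fork.direction,
                    "stalled": fork.stalled,
                    "true_speed_kb_min": fork.speed_kb_min,
                    "origin_pos_um": fork.origin_pos_um,
                    "truncated": fork.truncated,
                    "n_sibling_tracks": tracks_per_origin[fork.origin_id],
                }
            )
        fibers.append(FiberTrack(fiber_id, segments, (0.0, length)))

    ground_truth = pd.DataFrame(gt_rows)
    return fibers, ground_truth


def _resolve_collisions(forks: list[_Fork], fiber_len: float) -> None:
    """Truncate converging tracks at the midpoint of any overlap and clip
    everything to the fiber extent."""
    tracked = [f for f in forks if f.idu is not None]
    tracked.sort(key=lambda f: f.origin_pos_um)

    def outer(f: _Fork) -> tuple[float, float]:
        lo = min(f.idu[0], f.cldu[0])
        hi = max(f.idu[1], f.cldu[1])
        return lo, hi

    # pairwise between forks ordered by extent start
    exts = sorted(tracked, key=lambda f: outer(f)[0])
    for a, b in zip(exts, exts[1:]):
        a_lo, a_hi = outer(a)
        b_lo, b_hi = outer(b)
        if a.origin_id == b.origin_id:
            continue  # siblings abut at the origin by construction
        if b_lo < a_hi:  # overlap
            boundary = 0.5 * (b_lo + a_hi)
            _truncate_right(a, boundary)
            _truncate_left(b, boundary)
    for f in tracked:
        if f.idu[0] < 0 or f.cldu[0] < 0:
            _truncate_left(f, 0.0)
        if f.idu[1] > fiber_len or f.cldu[1] > fiber_len:
            _truncate_right(f, fiber_len)


def _truncate_right(f: _Fork, boundary: float) -> None:
    for seg in (f.idu, f.cldu):
        if seg[1] > boundary or seg[0] > boundary:
            f.truncated = True
        seg[0] = min(seg[0], boundary)
        seg[1] = min(seg[1], boundary)


def _truncate_left(f: _Fork, boundary: float) -> None:
    for seg in (f.idu, f.cldu):
        if seg[0] < boundary or seg[1] < boundary:
            f.truncated = True
        seg[0] = max(seg[0], boundary)
        seg[1] = max(seg[1], boundary)
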