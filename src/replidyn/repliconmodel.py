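"""Closed-form replicon arithmetic and cell-cycle kinetics.

Connects the measured replication parameters of mouse embryonic stem cells —
genome size GS (nt, as a low/high range across reference-genome and flow
cytometry estimates), replication fork speed RFS (nt/min), inter-origin
distance IOD (nt), S-phase duration (min) and the number of replication
foci active in parallel N_RFi — through simple conservation arithmetic:

    one-fork replication time   = GS / RFS                        (hours)
    forks active in parallel    = GS / RFS / S-phase duration
    replicons active in parallel = forks / 2
    replicons per focus         = replicons / N_RFi
    calculated single-fork %    = 100 · (1 − replicons / N_RFi)
    total activated origins     = GS / IOD

A replicons-per-focus ratio below one means more foci are observed than
bidirectional replicons are needed, the shortfall being attributable to
unidirectional forks.  Values are kept at full precision internally and
rounded only at presentation (half-up to integers for counts and hours,
two decimals for the ratio, nearest hundred for total origins).

Kinetics: population doubling time from log2 growth curves and S-phase
(sub)stage durations as doubling time × stage fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .synthgen.growth import GrowthCurve

__all__ = [
    "ReplicionParams",
    "ReplicionDerived",
    "StageTally",
    "time_one_fork",
    "forks_parallel",
    "replicons_parallel",
    "replicons_per_rf",
    "pct_single_calc",
    "total_origins",
    "derive",
    "doubling_time",
    "stage_durations",
    "GrowthCurve",
]

Pair = tuple[float, float]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _round_hundred(x: float) -> int:
    return 100 * _round_half_up(x / 100.0)


def _as_pair(x) -> Pair:
    if isinstance(x, (tuple, list)):
        lo, hi = float(x[0]), float(x[1])
    else:
        lo = hi = float(x)
    if lo > hi:
        raise ValueError("range low endpoint exceeds high endpoint")
    return lo, hi


@dataclass
class ReplicionParams:
    """Measured inputs of the replicon model (genome size may be a range)."""

    genome_size_nt: Pair
    rfs_nt_min: float
    iod_nt: float
    s_phase_min: float
    n_rfi: float

    def __post_init__(self) -> None:
        self.genome_size_nt = _as_pair(self.genome_size_nt)
        for name in ("rfs_nt_min", "iod_nt", "s_phase_min", "n_rfi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.genome_size_nt[0] <= 0:
            raise ValueError("genome size must be strictly positive")


@dataclass
class ReplicionDerived:
    """Derived quantities, rounded for presentation, as (low, high) pairs.

    Note pct_single is antitone in genome size: its pair is ordered by
    genome-size endpoint, so low genome size maps to the first element."""

    t_one_fork_h: tuple[int, int]
    forks_parallel: tuple[int, int]
    replicons_parallel: tuple[int, int]
    replicons_per_rf: tuple[float, float]
    pct_single_calc: tuple[int, int]
    total_origins: tuple[int, int]
    # full-precision values, keyed by genome-size endpoint
    raw: dict = None


def time_one_fork(p: ReplicionParams) -> tuple[int, int]:
    """Hours to replicate the genome with a single fork: GS / RFS."""
    return tuple(
        _round_half_up(gs / p.rfs_nt_min / 60.0) for gs in p.genome_size_nt
    )


def forks_parallel(p: ReplicionParams) -> tuple[int, int]:
    """Forks that must be active in parallel: GS / RFS / S-phase duration."""
    return tuple(
        _round_half_up(gs / p.rfs_nt_min / p.s_phase_min) for gs in p.genome_size_nt
    )


def replicons_parallel(forks: float) -> int:
    """Bidirectional replicons active in parallel: forks / 2."""
    return _round_half_up(forks / 2.0)


def replicons_per_rf(replicons: float, n_rfi: float) -> float:
    """Calculated replicons active in parallel per counted replication
    focus, rounded to two decimals."""
    if n_rfi <= 0:
        raise ValueError("n_rfi must be positive")
    return round(replicons / n_rfi, 2)


def pct_single_calc(ratio_raw: float) -> int:
    """Calculated single-fork percentage, 100·(1 − replicons/RFi), from the
    *unrounded* ratio."""
    return _round_half_up(100.0 * (1.0 - ratio_raw))


def total_origins(p: ReplicionParams) -> tuple[int, int]:
    """Total origins activated during S-phase: GS / IOD, nearest hundred."""
    return tuple(_round_hundred(gs / p.iod_nt) for gs in p.genome_size_nt)


def derive(p: ReplicionParams) -> ReplicionDerived:
    """Compute every derived row at full precision, rounding only the
    presented values."""
    raw = {}
    for gs in p.genome_size_nt:
        forks = gs / p.rfs_nt_min / p.s_phase_min
        reps = forks / 2.0
        ratio = reps / p.n_rfi
        raw[gs] = {
            "t_one_fork_h": gs / p.rfs_nt_min / 60.0,
            "forks_parallel": forks,
            "replicons_parallel": reps,
            "replicons_per_rf": ratio,
            "pct_single_calc": 100.0 * (1.0 - ratio),
            "total_origins": gs / p.iod_nt,
        }
    lo, hi = p.genome_size_nt
    return ReplicionDerived(
        t_one_fork_h=time_one_fork(p),
        forks_parallel=forks_parallel(p),
        replicons_parallel=tuple(
            replicons_parallel(raw[gs]["forks_parallel"]) for gs in (lo, hi)
        ),
        replicons_per_rf=tuple(
            replicons_per_rf(raw[gs]["replicons_parallel"], p.n_rfi) for gs in (lo, hi)
        ),
        pct_single_calc=tuple(
            pct_single_calc(raw[gs]["replicons_per_rf"]) for gs in (lo, hi)
        ),
        total_origins=total_origins(p),
        raw=raw,
    )


# --------------------------------------------------------------------------
# cell-cycle kinetics


@dataclass
class StageTally:
    """Cell counts per cycle/stage category (S-phase substages I, II, III,
    Y, plus non-S and mitosis)."""

    counts: Mapping[str, float]
    s_phase_stages: tuple[str, ...] = ("I", "II", "III", "Y")

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative counts")
        if sum(self.counts.values()) <= 0:
            raise ValueError("total count must be positive")

    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()}

    def s_fraction(self) -> float:
        return sum(
            f for k, f in self.fractions().items() if k in self.s_phase_stages
        )


def doubling_time(curve: GrowthCurve) -> float:
    """Population doubling time in hours.

    Per time point x > 0, the doubling rate is log2(n_x / n_0) / t (with t
    in hours from the first point); rates are inverted to hours-per-doubling
    and averaged.  Non-increasing counts yield a negative (flagged) value.
    """
    if len(curve.times_h) < 2:
        raise ValueError("need at least two time points")
    if any(c <= 0 for c in curve.counts):
        raise ValueError("counts must be positive")
    t0, n0 = curve.times_h[0], curve.counts[0]
    per_point = []
    for t, n in zip(curve.times_h[1:], curve.counts[1:]):
        dt = t - t0
        if dt <= 0:
            raise ValueError("times must be strictly increasing")
        rate = math.log2(n / n0) / dt  # doublings per hour
        if rate == 0:
            return float("inf")
        per_point.append(1.0 / rate)
    return float(sum(per_point) / len(per_point))


def stage_durations(
    tally: StageTally, doubling_h: float
) -> dict[str, float]:
    """Hours spent per stage: doubling time × stage cell fraction.

    Also reports the aggregate S-phase duration under key ``"S"``."""
    if doubling_h <= 0:
        raise ValueError("doubling_h must be positive")
    out = {k: doubling_h * f for k, f in tally.fractions().items()}
    out["S"] = doubling_h * tally.s_fraction()
    return out
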