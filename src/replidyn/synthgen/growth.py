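"""Exponential growth-curve simulator for doubling-time analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class GrowthCurve:
    """Cell counts over time: parallel (time_h, count) sequences."""

    times_h: list[float]
    counts: list[float]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.counts):
            raise ValueError("times and counts differ in length")
        if any(t < 0 for t in self.times_h):
            raise ValueError("negative times")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative counts")


def simulate_growth(
    n0: float,
    doubling_h: float,
    times_h: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """counts = n0 · 2^(t / doubling_h) × lognormal noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal noise (median 1); 0 gives the exact exponential curve.
    """
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if doubling_h <= 0:
        raise ValueError("doubling_h must be positive")
    if any(t < 0 for t in times_h):
        raise ValueError("negative times")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    counts = []
    sigma = math.sqrt(math.log1p(noise_cv**2))
    for t in times_h:
        c = n0 * 2.0 ** (t / doubling_h)
        if noise_cv > 0:
            c *= float(rng.lognormal(mean=0.0, sigma=sigma))
        counts.append(c)
    return GrowthCurve(list(map(float, times_h)), counts)
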