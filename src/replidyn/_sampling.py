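"""Internal sampling helpers shared by the synthetic-data generators."""

from __future__ import annotations

import numpy as np
from scipy import stats


def check_truncation_mass(mean: float, sd: float, name: str) -> None:
    """Refuse configurations whose >0 truncation would reject more than half
    of the normal mass (a silently biased sample otherwise)."""
    if sd < 0:
        raise ValueError(f"{name}: negative sd")
    if sd == 0:
        if mean <= 0:
            raise ValueError(f"{name}: degenerate non-positive value")
        return
    if stats.norm.cdf(0.0, loc=mean, scale=sd) > 0.5:
        raise ValueError(
            f"{name}: truncated-normal rejection mass exceeds 50% "
            f"(mean={mean}, sd={sd})"
        )


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf) via rejection sampling."""
    if sd == 0:
        return np.full(size, float(mean))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        draw = draw[draw > 0]
        out[filled : filled + draw.size] = draw
        filled += draw.size
    return out
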