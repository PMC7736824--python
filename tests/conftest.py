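"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from replidyn import fiberkit, focikit
from replidyn.synthgen import (
    FiberSimConfig,
    ImageSimConfig,
    simulate_fibers,
    simulate_stacks,
)


@pytest.fixture(scope="session")
def sparse_fiber_run():
    """Fibers with well-separated origins (no fork merging) and no stalls:
    the clean regime in which classification should be exact."""
    cfg = FiberSimConfig(
        n_fibers=120,
        fiber_len_mean_um=2000.0,
        fiber_len_sd=100.0,
        iod_mean_kb=400.0,
        iod_sd_kb=16.0,
        speed_sd=0.2667,
        p_fork_stall=0.0,
        seed=101,
    )
    fibers, gt = simulate_fibers(cfg)
    return cfg, fibers, gt


@pytest.fixture(scope="session")
def sim_stack_run():
    """A SIM-regime stack with 300 well-spaced ground-truth foci."""
    cfg = ImageSimConfig(
        shape_zyx=(28, 320, 320),
        n_nuclei=2,
        nucleus_radius_um=3.2,
        n_foci=300,
        focus_sigma_nm=70.0,
        min_separation_nm=400.0,
        focus_amplitude=600.0,
        noise_sd=2.0,
        seed=5,
    )
    channels, gt = simulate_stacks(cfg)
    rep = focikit.isotropic_rescale(channels["replication"])
    dapi = focikit.isotropic_rescale(channels["dapi"])
    mask = focikit.segment_nuclei(dapi)
    return cfg, channels, gt, rep, dapi, mask


def make_fiber(segments, extent=(0.0, 100.0), fiber_id="f0"):
    return fiberkit.FiberTrack(
        fiber_id,
        [fiberkit.Segment(lab, a, b) for lab, a, b in segments],
        extent,
    )


@pytest.fixture
def fiber_factory():
    return make_fiber
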