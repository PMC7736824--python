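"""Synthetic multi-channel 3D stacks of replicating nuclei.

Generates anisotropic z-stacks emulating the channels used in replication
microscopy: a DAPI channel (nuclear counterstain with smooth texture and
bright chromocenter blobs) and a replication channel (nucleotide/PCNA
signal) in which each replication focus is a 3D Gaussian.  Foci are placed
in clusters — cluster sizes drawn from a configurable discrete law, members
scattered within a pseudo-widefield-scale radius — so that super-resolved
versus diffraction-limited counting can be exercised against ground truth.
Poisson shot noise plus Gaussian read noise is added to every channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from ..focikit import VoxelGrid


@dataclass(frozen=True)
class ClusterSizeLaw:
    """Named discrete distribution for nanofoci-per-cluster counts.

    Supported names: ``fixed`` (params: size), ``poisson`` (params: lam;
    conditioned on >= 1) and ``one_plus_poisson`` (1 + Poisson(lam))."""

    name: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.name not in ("fixed", "poisson", "one_plus_poisson"):
            raise ValueError(f"unknown cluster size law {self.name!r}")


def sample_cluster_sizes(
    law: ClusterSizeLaw, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if law.name == "fixed":
        return np.full(n, int(law.params["size"]), dtype=int)
    lam = float(law.params["lam"])
    if law.name == "one_plus_poisson":
        return 1 + rng.poisson(lam, size=n)
    # poisson conditioned on >= 1
    out = rng.poisson(lam, size=n)
    while np.any(out == 0):
        zeros = out == 0
        out[zeros] = rng.poisson(lam, size=int(zeros.sum()))
    return out


@dataclass
class ImageSimConfig:
    shape_zyx: tuple[int, int, int] = (24, 256, 256)
    voxel_nm_zyx: tuple[float, float, float] = (125.0, 40.0, 40.0)
    n_nuclei: int = 2
    nucleus_radius_um: float = 3.2
    #: z semi-axis (μm); None flattens the nucleus to fit the stack depth,
    #: as for cells grown on coverslips
    nucleus_z_radius_um: float | None = None
    n_foci: int = 150
    focus_sigma_nm: float = 80.0
    cluster_size_law: ClusterSizeLaw = field(
        default_factory=lambda: ClusterSizeLaw("fixed", {"size": 1})
    )
    cluster_radius_nm: float = 250.0
    n_chromocenters: int = 6
    background_level: float = 10.0
    nucleus_level: float = 80.0
    chromocenter_amplitude: float = 120.0
    chromocenter_sigma_nm: float = 400.0
    focus_amplitude: float = 500.0
    noise_sd: float = 2.0
    min_separation_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape_zyx):
            raise ValueError("shape dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_nm_zyx):
            raise ValueError("voxel sizes must be positive")
        if self.n_nuclei < 1 or self.nucleus_radius_um <= 0:
            raise ValueError("need at least one nucleus of positive radius")
        if self.n_foci < 0:
            raise ValueError("n_foci must be non-negative")
        if self.focus_sigma_nm <= 0:
            raise ValueError("focus_sigma_nm must be positive")


@dataclass
class StackGroundTruth:
    foci: pd.DataFrame  # focus_id, cluster_id, nucleus_id, z/y/x (voxel), z/y/x_nm
    nuclei: np.ndarray  # label volume, 0 = background
    nucleus_centers: pd.DataFrame
    chromocenters: pd.DataFrame


_MAX_TRIES = 2000


def simulate_stacks(
    cfg: ImageSimConfig,
) -> tuple[dict[str, VoxelGrid], StackGroundTruth]:
    """Simulate a DAPI and a replication channel plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape_zyx)
    voxel = np.asarray(cfg.voxel_nm_zyx, dtype=float)
    radius_nm = cfg.nucleus_radius_um * 1000.0
    z_radius_um = cfg.nucleus_z_radius_um
    if z_radius_um is None:
        z_extent_um = shape[0] * voxel[0] / 1000.0
        z_radius_um = min(cfg.nucleus_radius_um, 0.42 * z_extent_um)
    radius_vox = radius_nm / voxel  # per-axis semi-axes in voxels
    radius_vox[0] = z_radius_um * 1000.0 / voxel[0]

    centers = _place_nuclei(rng, shape, radius_vox, cfg.n_nuclei)
    labels = _nucleus_labels(shape, centers, radius_vox)

    dapi = np.full(shape, cfg.background_level, dtype=float)
    dapi[labels > 0] = cfg.background_level + cfg.nucleus_level
    # smooth intra-nuclear texture
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=2.0)
    dapi[labels > 0] += 0.15 * cfg.nucleus_level * texture[labels > 0]

    cc_rows = []
    cc_sigma_vox = cfg.chromocenter_sigma_nm / voxel
    for nid, c in enumerate(centers, start=1):
        for k in range(cfg.n_chromocenters):
            p = _point_in_nucleus(rng, c, radius_vox, margin=0.35)
            _add_gaussian(dapi, p, cc_sigma_vox, cfg.chromocenter_amplitude)
            cc_rows.append(
                {"nucleus_id": nid, "cc_id": f"n{nid}c{k}", "z": p[0], "y": p[1], "x": p[2]}
            )

    rep = np.full(shape, cfg.background_level, dtype=float)
    foci_rows = _place_foci(rng, cfg, centers, radius_vox, voxel)
    sigma_vox = cfg.focus_sigma_nm / voxel
    for row in foci_rows:
        _add_gaussian(rep, (row["z"], row["y"], row["x"]), sigma_vox, cfg.focus_amplitude)

    for img in (dapi, rep):
        noisy = rng.poisson(np.clip(img, 0, None)).astype(float)
        noisy += rng.normal(0.0, cfg.noise_sd, size=shape)
        img[...] = np.clip(noisy, 0, None)

    channels = {
        "dapi": VoxelGrid(dapi, tuple(voxel), "dapi"),
        "replication": VoxelGrid(rep, tuple(voxel), "replication"),
    }
    foci = pd.DataFrame(
        foci_rows,
        columns=["focus_id", "cluster_id", "nucleus_id", "z", "y", "x"],
    )
    if len(foci):
        for ax, vs in zip("zyx", voxel):
            foci[f"{ax}_nm"] = foci[ax] * vs
    gt = StackGroundTruth(
        foci=foci,
        nuclei=labels,
        nucleus_centers=pd.DataFrame(
            [{"nucleus_id": i + 1, "z": c[0], "y": c[1], "x": c[2]} for i, c in enumerate(centers)]
        ),
        chromocenters=pd.DataFrame(cc_rows),
    )
    return channels, gt


def _place_nuclei(rng, shape, radius_vox, n_nuclei):
    lo = radius_vox * 1.02
    hi = np.asarray(shape) - 1 - radius_vox * 1.02
    if np.any(hi < lo):
        raise ValueError("nucleus does not fit inside the stack")
    # restart the whole arrangement on failure: an unlucky early placement
    # can make the remaining nuclei unplaceable
    for _restart in range(50):
        centers: list[np.ndarray] = []
        for _ in range(n_nuclei):
            for _try in range(_MAX_TRIES // 10):
                c = rng.uniform(lo, hi)
                if all(
                    np.sum(((c - other) / (2 * radius_vox)) ** 2) > 1.0
                    for other in centers
                ):
                    centers.append(c)
                    break
            else:
                break
        if len(centers) == n_nuclei:
            return centers
    raise ValueError("could not place non-overlapping nuclei")


def _nucleus_labels(shape, centers, radius_vox):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    labels = np.zeros(shape, dtype=np.int32)
    for nid, c in enumerate(centers, start=1):
        d2 = (
            ((zz - c[0]) / radius_vox[0]) ** 2
            + ((yy - c[1]) / radius_vox[1]) ** 2
            + ((xx - c[2]) / radius_vox[2]) ** 2
        )
        labels[d2 <= 1.0] = nid
    return labels


def _point_in_nucleus(rng, center, radius_vox, margin=0.15):
    """Uniform point inside the nucleus ellipsoid shrunk by ``margin``."""
    for _ in range(_MAX_TRIES):
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) <= 1.0:
            return center + u * radius_vox * (1.0 - margin)
    raise RuntimeError("rejection sampling failed")  # pragma: no cover


def _place_foci(rng, cfg, centers, radius_vox, voxel):
    rows: list[dict] = []
    if cfg.n_foci == 0:
        return rows
    # generous feasibility guard: foci (with separation) must fit in nuclei
    if cfg.min_separation_nm > 0:
        vol_nm3 = (
            cfg.n_nuclei * 4.0 / 3.0 * np.pi * (cfg.nucleus_radius_um * 1000) ** 3
        )
        if cfg.n_foci * (cfg.min_separation_nm**3) > vol_nm3:
            raise ValueError("focus count infeasible within nuclei")
    placed_nm: list[np.ndarray] = []
    cluster_id = 0
    fid = 0
    while fid < cfg.n_foci:
        size = int(sample_cluster_sizes(cfg.cluster_size_law, 1, rng)[0])
        size = min(size, cfg.n_foci - fid)
        nid = int(rng.integers(1, cfg.n_nuclei + 1))
        ccenter = _point_in_nucleus(rng, centers[nid - 1], radius_vox, margin=0.2)
        for _m in range(size):
            for _try in range(_MAX_TRIES):
                offset_nm = rng.normal(0.0, cfg.cluster_radius_nm, size=3)
                p = ccenter + offset_nm / voxel
                rel = (p - centers[nid - 1]) / (radius_vox * 0.9)
                if np.sum(rel**2) > 1.0:
                    continue
                p_nm = p * voxel
                if cfg.min_separation_nm > 0 and any(
                    np.linalg.norm(p_nm - q) < cfg.min_separation_nm for q in placed_nm
                ):
                    continue
                break
            else:
                raise ValueError("focus count infeasible within nuclei")
            placed_nm.append(p_nm)
            rows.append(
                {
                    "focus_id": fid,
                    "cluster_id": cluster_id,
                    "nucleus_id": nid,
                    "z": float(p[0]),
                    "y": float(p[1]),
                    "x": float(p[2]),
                }
            )
            fid += 1
        cluster_id += 1
    return rows


def _add_gaussian(img, center, sigma_vox, amplitude):
    """Add an anisotropic (voxel-space) Gaussian blob in a local window."""
    center = np.asarray(center, dtype=float)
    sigma = np.asarray(sigma_vox, dtype=float)
    lo = np.maximum(np.floor(center - 4 * sigma).astype(int), 0)
    hi = np.minimum(np.ceil(center + 4 * sigma).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
    )
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma))
    img[tuple(slice(l, h) for l, h in zip(lo, hi))] += amplitude * np.exp(-0.5 * d2)
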