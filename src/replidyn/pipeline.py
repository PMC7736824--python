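"""End-to-end orchestration: simulate inputs, run every analysis stage and
emit per-module tables plus a consolidated Markdown report.

All randomness flows from one root seed (sub-seeds are derived per stage),
so re-running an archived configuration reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fiberkit, focikit, io, originmap, repliconmodel
from ._version import __version__
from .synthgen import (
    FiberSimConfig,
    ImageSimConfig,
    OriginSimConfig,
    simulate_fibers,
    simulate_growth,
    simulate_origin_maps,
    simulate_stacks,
)

log = logging.getLogger("replidyn")


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # stage toggles
    run_fibers: bool = True
    run_origins: bool = True
    run_foci: bool = False  # imaging stage is the slow one; opt in
    run_model: bool = True
    # module parameters
    fiber_cfg: dict = field(default_factory=dict)
    origin_cfg: dict = field(default_factory=dict)
    image_cfg: dict = field(default_factory=dict)
    pulse_min: float = 15.0
    stretch_kb_per_um: float = 2.0
    cluster_bp: int = 22_000
    min_support: int = 2
    genome_size_nt: tuple = (5.19e9, 6.5e9)
    rfs_nt_min: float = 1670.0
    iod_nt: float = 90_000.0
    s_phase_min: float = 654.0
    n_rfi: float = 3320.0
    doubling_h: float = 14.0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and log
        verbosity excluded, so archival copies compare equal)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subseed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the consolidated summary.

    Writes per-stage CSV/JSON under ``cfg.out_dir`` and a Markdown report
    (``report.md``) with a provenance block.  A stage failure raises
    :class:`StageFailure`, keeping outputs of the completed stages.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "replidyn_version": __version__,
        }
    }
    sections: list[str] = []

    if cfg.run_fibers:
        _stage("fibers", _run_fibers, cfg, out, summary, sections)
    if cfg.run_origins:
        _stage("origins", _run_origins, cfg, out, summary, sections)
    if cfg.run_foci:
        _stage("foci", _run_foci, cfg, out, summary, sections)
    if cfg.run_model:
        _stage("model", _run_model, cfg, out, summary, sections)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    report = ["# replidyn pipeline report", ""]
    prov = summary["provenance"]
    report += [
        f"- config hash: `{prov['config_hash']}`",
        f"- seed: {prov['seed']}",
        f"- version: {prov['replidyn_version']}",
        "",
    ]
    report += sections
    (out / "report.md").write_text("\n".join(report))
    (out / "config.json").write_text(cfg.to_json())
    return summary


def _stage(name, fn, cfg, out, summary, sections):
    log.info("running stage %s", name)
    try:
        summary[name], text = fn(cfg, out)
        sections.extend(text)
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise StageFailure(name, exc) from exc


def _run_fibers(cfg: RunConfig, out: Path):
    fib_cfg = FiberSimConfig(seed=_subseed(cfg.seed, "fibers"), **cfg.fiber_cfg)
    fibers, gt = simulate_fibers(fib_cfg)
    io.write_fibers(fibers, out / "fibers.tsv")
    gt.to_csv(out / "fibers_ground_truth.csv", index=False)
    forks = fiberkit.classify_tracks(fibers)
    origins = fiberkit.call_origins(forks)
    s = fiberkit.summarize_combing(
        forks, origins, pulse_min=cfg.pulse_min, stretch_kb_per_um=cfg.stretch_kb_per_um
    )
    pd.DataFrame([dataclasses.asdict(f) for f in forks]).to_csv(
        out / "fork_measurements.csv", index=False
    )
    stats = {
        "rfs_mean_kb_min": s.rfs_mean,
        "rfs_sem": s.rfs_sem,
        "iod_mean_kb": s.iod_mean,
        "iod_sem": s.iod_sem,
        "pct_unidirectional": s.pct_unidirectional,
        "n_forks": s.n_forks,
        "n_origins": s.n_origins,
    }
    text = [
        "## Combing",
        "",
        f"- mean fork speed: {s.rfs_mean:.3f} kb/min (n={s.n_forks})",
        f"- mean inter-origin distance: {s.iod_mean:.1f} kb" if s.iod_mean else "- no IOD pairs",
        f"- unidirectional structures: {s.pct_unidirectional:.2f}%"
        if s.pct_unidirectional is not None
        else "- no fork structures",
        "",
    ]
    return stats, text


def _run_origins(cfg: RunConfig, out: Path):
    base = dict(chrom_sizes={"chr1": 30_000_000, "chr2": 20_000_000})
    base.update(cfg.origin_cfg)
    ori_cfg = OriginSimConfig(seed=_subseed(cfg.seed, "origins"), **base)
    replicates, zones_gt = simulate_origin_maps(ori_cfg)
    for rid, peaks in replicates.items():
        io.write_bed(peaks, out / f"origins_rep{rid}.bed")
    peaks = originmap.reproducible_peaks(
        list(replicates.values()), min_support=cfg.min_support
    )
    zones = originmap.cluster_initiation_sites(peaks, cluster_bp=cfg.cluster_bp)
    dist = originmap.iod_from_zones(zones)
    originmap.per_chromosome_summary(dist).to_csv(
        out / "iod_per_chromosome.csv", index=False
    )
    io.write_bed([(z.chrom, z.start, z.end) for z in zones], out / "zones.bed")
    stats = {
        "n_reproducible_peaks": len(peaks),
        "n_zones": len(zones),
        "iod_mean_bp": dist.mean,
        "iod_median_bp": dist.median,
        "n_omitted_gap_spanning": dist.n_omitted_gap_spanning,
    }
    text = [
        "## Origin maps",
        "",
        f"- reproducible peaks: {len(peaks)}",
        f"- initiation zones (cluster {cfg.cluster_bp/1000:.0f} kb): {len(zones)}",
        f"- mean IOD: {dist.mean/1000:.1f} kb",
        "",
    ]
    return stats, text


def _run_foci(cfg: RunConfig, out: Path):
    img_cfg = ImageSimConfig(seed=_subseed(cfg.seed, "foci"), **cfg.image_cfg)
    channels, gt = simulate_stacks(img_cfg)
    rep = focikit.isotropic_rescale(channels["replication"])
    dapi = focikit.isotropic_rescale(channels["dapi"])
    mask = focikit.segment_nuclei(dapi)
    records = focikit.segment_foci(rep, mask, regime="sim")
    table, vector = focikit.focus_features(records, {"replication": rep, "dapi": dapi}, mask)
    table.to_csv(out / "focus_features.csv", index=False)
    stats = {
        "n_true_foci": int(len(gt.foci)),
        "n_detected_foci": len(records),
        "n_nuclei": len(mask.ids()),
    }
    text = [
        "## Replication foci",
        "",
        f"- ground-truth foci: {stats['n_true_foci']}; detected: {stats['n_detected_foci']}",
        "",
    ]
    return stats, text


def _run_model(cfg: RunConfig, out: Path):
    params = repliconmodel.ReplicionParams(
        genome_size_nt=tuple(cfg.genome_size_nt),
        rfs_nt_min=cfg.rfs_nt_min,
        iod_nt=cfg.iod_nt,
        s_phase_min=cfg.s_phase_min,
        n_rfi=cfg.n_rfi,
    )
    derived = repliconmodel.derive(params)
    curve = simulate_growth(
        2e5, cfg.doubling_h, [0, 24, 48, 72, 96], noise_cv=0.0,
        seed=_subseed(cfg.seed, "growth"),
    )
    io.write_growth(curve, out / "growth.csv")
    td = repliconmodel.doubling_time(curve)
    stats = {
        "t_one_fork_h": derived.t_one_fork_h,
        "forks_parallel": derived.forks_parallel,
        "replicons_parallel": derived.replicons_parallel,
        "replicons_per_rf": derived.replicons_per_rf,
        "pct_single_calc": derived.pct_single_calc,
        "total_origins": derived.total_origins,
        "doubling_h": td,
    }
    rows = [
        ("Time to replicate the genome with one fork (h)", derived.t_one_fork_h),
        ("Replication forks active in parallel", derived.forks_parallel),
        ("Replicons active in parallel", derived.replicons_parallel),
        ("Replicons per replication focus", derived.replicons_per_rf),
        ("Calculated single forks (%)", derived.pct_single_calc),
        ("Total activated origins", derived.total_origins),
    ]
    text = ["## Replicon model", "", "| quantity | low GS | high GS |", "|---|---|---|"]
    text += [f"| {name} | {lo} | {hi} |" for name, (lo, hi) in rows]
    text += ["", f"- doubling time from growth curve: {td:.2f} h", ""]
    pd.DataFrame(
        [(n, lo, hi) for n, (lo, hi) in rows], columns=["quantity", "low", "high"]
    ).to_csv(out / "replicon_model.csv", index=False)
    return stats, text
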