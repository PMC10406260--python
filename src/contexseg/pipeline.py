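"""End-to-end scaled-down replication driver.

``replicate_small`` runs phantom generation -> modification grid ->
saliency report as one deterministic pipeline, writing per-tissue
heatmap CSVs/PNGs, an extremes summary, the saliency panel, and a run
manifest (config hash, seed, per-stage outputs with content hashes).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import PipelineConfig, config_to_dict
from .dataset import StudyData, build_study_data
from .grid import (
    GridConfig,
    GridResult,
    locate_extremes,
    plot_heatmaps,
    save_heatmaps,
    settings_axis,
)
from .io import file_sha256, write_json
from .phantom import Protocol, enumerate_protocols
from .saliency import attention_report, plot_attention_report


def config_hash(cfg: PipelineConfig) -> str:
    payload = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def subsample_protocols(
    protocols: list[Protocol], n: int
) -> list[Protocol]:
    """n evenly spaced protocols from an ordered protocol list."""
    if n >= len(protocols):
        return list(protocols)
    idx = np.round(np.linspace(0, len(protocols) - 1, n)).astype(int)
    return [protocols[i] for i in idx]


def representative_protocol(
    protocols: list[Protocol], tr_ms: float, te_ms: float
) -> Protocol:
    """The protocol nearest (scaled Euclidean) to the requested (TR, TE)."""
    trs = np.array([p.tr_ms for p in protocols])
    tes = np.array([p.te_ms for p in protocols])
    tr_span = np.ptp(trs) or 1.0
    te_span = np.ptp(tes) or 1.0
    d = ((trs - tr_ms) / tr_span) ** 2 + ((tes - te_ms) / te_span) ** 2
    return protocols[int(np.argmin(d))]


@dataclass
class ReplicationResult:
    """In-memory handle on everything ``replicate_small`` produced."""

    config: PipelineConfig
    data: StudyData
    grid_result: GridResult
    extremes: dict
    report: dict
    out_dir: Path
    files: dict[str, str] = field(default_factory=dict)


def replicate_small(
    cfg: PipelineConfig,
    out_dir: str | Path,
    progress: bool = False,
    overwrite: bool = False,
) -> ReplicationResult:
    """Run the scaled-down study end to end, deterministically in
    ``cfg.seed``.

    Refuses to reuse an output directory whose manifest records a
    different config hash (no silent overwrites), unless ``overwrite``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != chash:
            raise FileExistsError(
                f"{out} holds results for config {previous.get('config_hash')}"
                f", not {chash}; pass overwrite=True or use a fresh directory"
            )
    manifest: dict = {
        "config_hash": chash,
        "seed": cfg.seed,
        "config": config_to_dict(cfg),
        "stages": {},
    }

    def _stage(name: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 2),
            "outputs": {str(p.relative_to(out)): file_sha256(p)
                        for p in outputs},
        }
        write_json(manifest, manifest_path)

    # stage 1: data
    t0 = time.time()
    all_protocols = enumerate_protocols(cfg.data.tr_range, cfg.data.te_range)
    protocols = subsample_protocols(all_protocols, cfg.data.n_protocols)
    data = build_study_data(
        protocols,
        n_subjects=cfg.data.n_subjects,
        size=cfg.data.size,
        noise_sigma=cfg.data.noise_sigma,
        variability=cfg.data.variability,
        ratio=cfg.data.ratio,
        seed=cfg.seed,
    )
    manifest_csv = out / "dataset_manifest.csv"
    data.manifest().to_csv(manifest_csv, index=False)
    _stage("make-data", t0, [manifest_csv])

    # stage 2: grid
    t0 = time.time()
    axis = settings_axis(cfg.grid.kind, cfg.grid.strengths)
    grid_cfg = GridConfig(
        train_settings=axis,
        test_settings=axis,
        protocols=tuple(protocols),
        n_runs=cfg.grid.n_runs,
        base_seed=cfg.seed,
        model_cfg=cfg.model,
        train_cfg=cfg.train,
    )
    from .grid import run_grid

    grid_result = run_grid(grid_cfg, data, cache_dir=out / "cache",
                           progress=progress)
    csvs = save_heatmaps(grid_result, out)
    pngs = plot_heatmaps(grid_result, out)
    mean_matrix = grid_result.mean_matrix()
    mean_csv = out / "heatmap_mean.csv"
    mean_matrix.to_csv(mean_csv, float_format="%.6f")
    extremes = locate_extremes(mean_matrix)
    extremes_path = write_json(
        {k: {"train": v[0], "test": v[1], "mean_dsc": v[2]}
         for k, v in extremes.items()},
        out / "extremes.json",
    )
    _stage("run-grid", t0, csvs + pngs + [mean_csv, extremes_path])

    # stage 3: saliency report on the representative protocol
    t0 = time.time()
    rep = representative_protocol(
        protocols, cfg.saliency.representative_tr_ms,
        cfg.saliency.representative_te_ms,
    )
    rep_image = next(im for im in data.test if im.protocol == rep)
    cases = {
        "best": extremes["best"][:2],
        "original": ("Ori", "Ori"),
        "worst": extremes["worst"][:2],
        "opposite_bad": extremes["opposite_bad"][:2],
    }
    report = attention_report(grid_result, rep_image, cases,
                              n_steps=cfg.saliency.n_steps)
    panel_path = out / "attention_report.png"
    plot_attention_report(report, panel_path)
    _stage("saliency", t0, [panel_path])

    files = {
        name: str(p)
        for stage in manifest["stages"].values()
        for name, p in stage["outputs"].items()
    }
    return ReplicationResult(
        config=cfg, data=data, grid_result=grid_result, extremes=extremes,
        report=report, out_dir=out, files=files,
    )
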