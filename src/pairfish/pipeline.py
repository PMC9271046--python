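"""Config-driven orchestration: simulate -> detect -> pair -> count -> stats.

Each stage consumes and produces the documented CSV/TIFF artifacts in a run
directory.  A single global seed drives everything; per-stage sub-seeds are
derived by CRC-32 hashing of ``"<seed>:<stage>"`` so stages are individually
reproducible.  ``run_all`` emits a manifest with the config hash, seed,
package version and a checksum per output file; re-running with the same
config and seed reproduces the checksums bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path

import pandas as pd

from . import __version__
from .config import GERMLINE_STAGES, PipelineConfig, dump_config
from .detect import count_dots_for_cells, detect_loci
from .expression import silencing_index, stage_profile
from .io import read_cells, read_fields, read_table, write_table
from .pairing import (classify_pairing_table, normalize_to_cysc,
                      paired_unpaired_ratio, summarize_pairing_by_stage)
from .scene import generate_scene
from .stats import distribution_summary, multi_group_vs_control

LOCUS_CHANNELS = ("dna", "intron")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (documented hashing rule)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulate(config: PipelineConfig, out_dir: Path) -> Path:
    scene_cfg = dataclasses.replace(config.scene,
                                    seed=derive_seed(config.seed, "simulate"))
    scene = generate_scene(scene_cfg)
    scene_dir = out_dir / "scene"
    scene.write(scene_dir)
    return scene_dir


def _load_scene_dir(out_dir: Path):
    scene_dir = out_dir / "scene"
    fields = read_fields(scene_dir)
    n_planes = fields[0].stack.n_planes if fields else None
    cells = read_cells(scene_dir / "cells.csv", n_planes=n_planes)
    return fields, cells


def run_detect(config: PipelineConfig, out_dir: Path) -> list[Path]:
    fields, cells = _load_scene_dir(out_dir)
    paths = []
    for channel in LOCUS_CHANNELS:
        spots = detect_loci(fields, cells, channel, config.detection)
        paths.append(write_table(spots, out_dir / f"spots_{channel}.csv"))
    return paths


def run_pair(config: PipelineConfig, out_dir: Path) -> list[Path]:
    fields, cells = _load_scene_dir(out_dir)
    z_step = fields[0].stack.z_step_um
    paths = []
    for channel in LOCUS_CHANNELS:
        spots = read_table(out_dir / f"spots_{channel}.csv")
        calls = classify_pairing_table(spots, cells, z_step, config.pairing)
        paths.append(write_table(calls, out_dir / f"pairing_{channel}.csv"))
        summary = summarize_pairing_by_stage(
            calls[calls["stage"].isin(GERMLINE_STAGES)],
            stage_order=tuple(s for s in GERMLINE_STAGES
                              if s in set(calls["stage"])))
        paths.append(write_table(summary, out_dir / f"pairing_summary_{channel}.csv"))
    # nascent intensity normalization on the intron channel
    spots = read_table(out_dir / "spots_intron.csv")
    calls = read_table(out_dir / "pairing_intron.csv")
    if (calls.query("stage == 'CySC' and state == 'paired'")
            .groupby("field").size().ge(2).all()):
        norm = normalize_to_cysc(spots, calls,
                                 seed=derive_seed(config.seed, "pair"))
        paths.append(write_table(norm, out_dir / "normalized_intron.csv"))
        ratio = paired_unpaired_ratio(
            norm, stage="GB", n_boot=config.bootstrap_resamples,
            seed=derive_seed(config.seed, "ratio"))
        ratio_df = pd.DataFrame([{k: str(v) if isinstance(v, tuple) else v
                                  for k, v in ratio.items()}])
        paths.append(write_table(ratio_df, out_dir / "ratio_intron.csv"))
    return paths


def run_count(config: PipelineConfig, out_dir: Path) -> list[Path]:
    fields, cells = _load_scene_dir(out_dir)
    counts = count_dots_for_cells(fields, cells, "exon", config.detection,
                                  mode="midplane")
    paths = [write_table(counts, out_dir / "counts_midplane.csv"),
             write_table(stage_profile(counts), out_dir / "stage_profile.csv")]
    stages = config.si_stages
    have = counts.groupby("stage").size()
    if all(have.get(s, 0) >= config.min_cells_per_stage for s in stages):
        si = silencing_index(counts, stages, n_boot=config.bootstrap_resamples,
                             seed=derive_seed(config.seed, "count"),
                             min_n=config.min_cells_per_stage)
        paths.append(write_table(pd.DataFrame([dataclasses.asdict(si)]),
                                 out_dir / "silencing_index.csv"))
    return paths


def run_stats(config: PipelineConfig, out_dir: Path,
              control: str = "GSC") -> list[Path]:
    counts = read_table(out_dir / "counts_midplane.csv")
    groups = {s: g["count"].to_numpy()
              for s, g in counts.groupby("stage") if len(g) >= 2}
    paths = []
    if control in groups and len(groups) >= 2:
        results = multi_group_vs_control(groups, control)
        paths.append(write_table(
            pd.DataFrame([dataclasses.asdict(r) for r in results]),
            out_dir / "comparisons_counts.csv"))
    paths.append(write_table(distribution_summary(groups),
                             out_dir / "count_distributions.csv"))
    return paths


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write a checksummed run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_path = dump_config(config, out_dir / "pipeline_config.json")
    stages = {
        "simulate": lambda: [run_simulate(config, out_dir)],
        "detect": lambda: run_detect(config, out_dir),
        "pair": lambda: run_pair(config, out_dir),
        "count": lambda: run_count(config, out_dir),
        "stats": lambda: run_stats(config, out_dir),
    }
    outputs: list[Path] = []
    for name, fn in stages.items():
        try:
            produced = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        for p in produced:
            p = Path(p)
            if p.is_dir():
                outputs.extend(sorted(q for q in p.rglob("*") if q.is_file()))
            else:
                outputs.append(p)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _sha256(cfg_path),
        "outputs": {str(p.relative_to(out_dir)): _sha256(p)
                    for p in sorted(set(outputs))},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
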