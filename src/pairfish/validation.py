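"""End-to-end benchmark protocols on ground-truthed synthetic scenes.

Each function generates a scene whose truth encodes a known effect, pushes
it through the full measurement pipeline (render -> detect -> classify /
count -> summarize) and returns the recovered quantity next to the truth.
These are the protocols behind the package's validation suite and the
reproduction script; they are ordinary library code and can be pointed at
other configurations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import DetectionParams, SceneConfig
from .detect import count_dots_for_cells, detect_loci
from .expression import SilencingIndex, silencing_index
from .pairing import classify_pairing_table, normalize_to_cysc, paired_unpaired_ratio
from .scene import Scene, generate_scene
from .stats import multi_group_vs_control

#: GB-only pairing probabilities for the intensity-ratio protocol: half the
#: gonialblasts paired, CySC references always paired
_RATIO_PAIRING = {"GSC": 0.85, "GB": 0.5, "SG2_4": 0.35, "SG8_16": 0.5,
                  "SC": 0.9, "CySC": 1.0}


def ratio_scene(seed: int, n_gb: int = 200, n_cysc: int | None = None,
                suppression_factor: float = 1.0) -> Scene:
    """G2-phase gonialblast field for paired-vs-unpaired intensity analysis.

    Half the GBs carry colocalized alleles (one punctum), half are unpaired
    with the alleles at least 1.5 um apart (well above the resolution limit);
    per-allele label is drawn from one common distribution in both groups,
    scaled by ``suppression_factor`` on the unpaired nascent output.  By
    default three paired CySC reference cells are provisioned per field of
    view so every field supports internal-control normalization.
    """
    if n_cysc is None:
        n_cysc = 3 * int(np.ceil(n_gb / 22))
    cfg = SceneConfig(
        n_cells_per_stage={"GSC": 0, "GB": n_gb, "SG2_4": 0, "SG8_16": 0,
                           "SC": 0, "CySC": n_cysc},
        pairing_prob=_RATIO_PAIRING,
        unpaired_distance_dist=(2.0, 0.3), unpaired_distance_min=1.5,
        sister_split_prob=0.0, suppression_factor=suppression_factor,
        seed=seed,
    )
    return generate_scene(cfg)


def measure_ratio(scene: Scene, channel: str, seed: int,
                  params: DetectionParams | None = None) -> dict:
    """Full-pipeline paired/unpaired intensity ratios for one locus channel."""
    params = params or DetectionParams()
    spots = detect_loci(scene.fields, scene.cells, channel, params)
    z_step = scene.fields[0].stack.z_step_um
    calls = classify_pairing_table(spots, scene.cells, z_step)
    norm = normalize_to_cysc(spots, calls, seed=seed)
    return paired_unpaired_ratio(norm, stage="GB", seed=seed + 1)


def detection_metrics(scene: Scene, channel: str = "dna",
                      params: DetectionParams | None = None,
                      lateral_tol_um: float = 0.2,
                      axial_tol_um: float = 0.6) -> dict:
    """Recall and precision of spot detection against the scene's truth."""
    params = params or DetectionParams()
    detected = detect_loci(scene.fields, scene.cells, channel, params)
    truth = scene.truth.spots.query("channel == @channel")
    used: set = set()
    matched = 0
    for r in detected.itertuples():
        cand = truth[truth["field"] == r.field]
        d_lat = np.hypot(cand["x_um"] - r.x_um, cand["y_um"] - r.y_um)
        d_z = np.abs(cand["z_um"] - r.z_um)
        ok = cand[(d_lat < lateral_tol_um) & (d_z < axial_tol_um)]
        ok = ok[~ok.index.isin(used)]
        if len(ok):
            used.add(ok.index[0])
            matched += 1
    return dict(
        recall=matched / len(truth) if len(truth) else float("nan"),
        precision=matched / len(detected) if len(detected) else float("nan"),
        n_truth=len(truth), n_detected=len(detected),
    )


def si_scene(seed: int, rate_gsc: float = 12.0, rate_sg: float = 6.0,
             n_per_stage: int = 200) -> Scene:
    """GSC + 2-4-SG field for end-to-end silencing-index recovery."""
    rates = {"GSC": rate_gsc, "GB": 9.0, "SG2_4": rate_sg, "SG8_16": 5.0,
             "SC": 4.0, "CySC": 8.0}
    cfg = SceneConfig(
        n_cells_per_stage={"GSC": n_per_stage, "GB": 0, "SG2_4": n_per_stage,
                           "SG8_16": 0, "SC": 0, "CySC": 0},
        mrna_rate=rates, seed=seed,
    )
    return generate_scene(cfg)


def measure_si(scene: Scene, seed: int,
               params: DetectionParams | None = None,
               mode: str = "midplane") -> SilencingIndex:
    """Detect and count smFISH dots, then compute the GSC/2-4SG SI."""
    params = params or DetectionParams()
    counts = count_dots_for_cells(scene.fields, scene.cells, "exon", params,
                                  mode=mode)
    return silencing_index(counts, ("GSC", "SG2_4"), seed=seed)


def hemizygote_single_focus_fraction(seed: int, n_cells: int = 250,
                                     sister_split_prob: float = 0.1,
                                     params: DetectionParams | None = None
                                     ) -> dict:
    """Fraction of single-focus pairing calls in a one-allele (hemizygote)
    scene where each locus occasionally resolves as two sister sub-foci."""
    params = params or DetectionParams()
    per = n_cells // 3
    cfg = SceneConfig(
        n_cells_per_stage={"GSC": per, "GB": per, "SG2_4": n_cells - 2 * per,
                           "SG8_16": 0, "SC": 0, "CySC": 0},
        n_alleles=1, sister_split_prob=sister_split_prob, seed=seed,
    )
    scene = generate_scene(cfg)
    spots = detect_loci(scene.fields, scene.cells, "dna", params)
    z_step = scene.fields[0].stack.z_step_um
    calls = classify_pairing_table(spots, scene.cells, z_step)
    frac = float((calls["n_foci"] == 1).mean())
    return dict(single_focus_fraction=frac, n=len(calls),
                truth_split_fraction=float(
                    (scene.truth.cells["true_n_foci"] >= 2).mean()))


def copy_number_counts(seed: int, rate_per_copy: float = 6.0,
                       n_per_level: int = 60,
                       params: DetectionParams | None = None):
    """Mid-plane counts over scenes whose mRNA rate scales with gene dosage."""
    import pandas as pd
    params = params or DetectionParams()
    frames = []
    for copy in (1, 2, 3):
        cfg = SceneConfig(
            n_cells_per_stage={"GSC": n_per_level, "GB": 0, "SG2_4": 0,
                               "SG8_16": 0, "SC": 0, "CySC": 0},
            mrna_rate=rate_per_copy * copy, seed=seed + copy,
        )
        scene = generate_scene(cfg)
        counts = count_dots_for_cells(scene.fields, scene.cells, "exon",
                                      params, mode="midplane")
        counts["copy_number"] = copy
        frames.append(counts)
    return pd.concat(frames, ignore_index=True)


def sidak_familywise_error(seed: int, n_reps: int = 1000, n_groups: int = 4,
                           n_per_group: int = 10, alpha: float = 0.05) -> dict:
    """Empirical family-wise error of Sidak-adjusted Welch tests under a
    global null (all groups drawn from one distribution)."""
    rng = np.random.default_rng(seed)
    false_families = 0
    for _ in range(n_reps):
        groups = {f"g{i}": rng.normal(0.0, 1.0, n_per_group)
                  for i in range(n_groups)}
        results = multi_group_vs_control(groups, "g0")
        if any(r.adjusted_p < alpha for r in results):
            false_families += 1
    fwer = false_families / n_reps
    return dict(fwer=fwer, n_reps=n_reps,
                se=float(np.sqrt(alpha * (1 - alpha) / n_reps)))


def default_detection(scene: Scene) -> DetectionParams:
    """Detection parameters matched to a scene's configured PSF."""
    return dataclasses.replace(DetectionParams(),
                               sigma_um=tuple(scene.config.psf_sigma))
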