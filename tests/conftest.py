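"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import pairfish as pf


@pytest.fixture(scope="session")
def small_scene() -> pf.Scene:
    """A small mixed-stage scene with every feature enabled (noise,
    contamination, sister splits), for I/O and sanity tests."""
    cfg = pf.SceneConfig(
        n_cells_per_stage={"GSC": 4, "GB": 4, "SG2_4": 4, "SG8_16": 0,
                           "SC": 0, "CySC": 4},
        seed=7,
    )
    return pf.generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_scene() -> pf.Scene:
    """Noise-free, contamination-free, split-free scene with well separated
    unpaired loci — the oracle scene for exact-recovery tests."""
    cfg = pf.SceneConfig(
        n_cells_per_stage={"GSC": 6, "GB": 6, "SG2_4": 6, "SG8_16": 0,
                           "SC": 0, "CySC": 4},
        mrna_rate=2.0,
        contamination_rate=0.0,
        sister_split_prob=0.0,
        unpaired_distance_dist=(1.8, 0.4),
        unpaired_distance_min=1.0,
        noise=pf.NoiseParams(background=0.0, gaussian_sd=0.0, poisson=False),
        seed=11,
    )
    return pf.generate_scene(cfg)


def match_spots(detected, truth, lateral_tol_um=0.2, axial_tol_um=0.6):
    """Greedy one-to-one matching of detections to ground-truth spots.

    Returns (n_matched, n_detected, n_truth).
    """
    used = set()
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
    return matched, len(detected), len(truth)
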