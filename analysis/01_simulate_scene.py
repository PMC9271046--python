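#!/usr/bin/env python
"""Simulate a wild-type-like testis-tip scene and summarize its ground truth.

Generates a mixed-stage field set with the default conditions (stage-specific
pairing probabilities, ~2-fold GSC -> 2-4SG mRNA decline, surface
contamination, Poisson + read noise) and writes per-stage truth summaries.
Image stacks are kept in memory; only tables leave this script.

Writes: results/01_truth_by_stage.csv, results/01_scene_config.json
"""

from pathlib import Path

import pairfish as pf
from pairfish.config import dump_config

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = pf.SceneConfig(
    n_cells_per_stage={"GSC": 20, "GB": 20, "SG2_4": 20, "SG8_16": 12,
                       "SC": 8, "CySC": 12},
    seed=20,
)
scene = pf.generate_scene(cfg)

truth = scene.truth.cells
by_stage = truth.groupby("stage").agg(
    n=("cell_id", "size"),
    paired_fraction=("true_state", lambda s: (s == "paired").mean()),
    mean_mid_dots=("true_mid_dots", "mean"),
    mean_wholecell_dots=("true_wholecell_dots", "mean"),
    mean_contamination=("contamination_dots", "mean"),
).reset_index()
by_stage.to_csv(OUT / "01_truth_by_stage.csv", index=False)
dump_config(cfg, OUT / "01_scene_config.json")

print(f"generated {len(scene.fields)} fields, {len(truth)} cells")
print(by_stage.to_string(index=False))
print("\nThe configured ~2-fold GSC->SG2_4 mRNA decline and the high "
      "stem-cell pairing fraction are visible in the truth table above; "
      "downstream scripts must recover them from the rendered images alone.")
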