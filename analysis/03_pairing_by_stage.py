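#!/usr/bin/env python
"""Recover stage-specific pairing fractions and inter-allele distances.

Classifies every cell's DNA-FISH pattern (single punctum = paired at
distance 0; two puncta = unpaired at D = sqrt(x^2 + z^2); 3+ = excluded)
and compares the per-stage paired fraction with the generator's configured
probabilities.

Writes: results/03_pairing_by_stage.csv
"""

from pathlib import Path

import pairfish as pf

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = pf.SceneConfig(
    n_cells_per_stage={"GSC": 40, "GB": 40, "SG2_4": 40, "SG8_16": 0,
                       "SC": 0, "CySC": 10},
    seed=40,
)
scene = pf.generate_scene(cfg)
spots = pf.detect_loci(scene.fields, scene.cells, "dna")
calls = pf.classify_pairing_table(spots, scene.cells, 0.5)
summary = pf.summarize_pairing_by_stage(
    calls[calls["stage"] != "CySC"], stage_order=("GSC", "GB", "SG2_4"))
summary["configured_pairing_prob"] = summary["stage"].map(cfg.pairing_prob)
summary.to_csv(OUT / "03_pairing_by_stage.csv", index=False)

print(summary.to_string(index=False))
print("\nThe recovered paired fractions track the configured per-stage "
      "probabilities (high in GSCs, low after differentiation), and paired "
      "cells contribute distance 0 by the single-punctum convention.")
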