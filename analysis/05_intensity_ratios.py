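#!/usr/bin/env python
"""Paired vs unpaired punctum intensities and suppression-factor recovery.

On gonialblast scenes with half-paired loci:
  * DNA channel, equal per-allele label      -> per-punctum ratio ~ 2:1
  * intron channel, pairing-independent rate -> per-punctum ratio ~ 2:1
  * intron channel, unpaired alleles at 60%  -> per-allele unpaired/paired
    ratio recovers ~0.6 (the suppression signature)

Writes: results/05_intensity_ratios.json
"""

import json
from pathlib import Path

from pairfish import validation as val

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def tidy(r):
    return {k: (round(v, 4) if isinstance(v, float) else
                tuple(round(x, 4) for x in v) if isinstance(v, tuple) else v)
            for k, v in r.items()}


report = {}
scene = val.ratio_scene(seed=60, n_gb=120, suppression_factor=1.0)
report["dna_equal_label"] = tidy(val.measure_ratio(scene, "dna", seed=61))
report["intron_no_suppression"] = tidy(val.measure_ratio(scene, "intron",
                                                         seed=62))
del scene

scene = val.ratio_scene(seed=63, n_gb=120, suppression_factor=0.6)
report["intron_suppression_0.6"] = tidy(val.measure_ratio(scene, "intron",
                                                          seed=64))

(OUT / "05_intensity_ratios.json").write_text(json.dumps(report, indent=2))
for name, r in report.items():
    print(f"{name}: per-punctum paired/unpaired = {r['per_punctum_ratio']}, "
          f"per-allele unpaired/paired = {r['per_allele_ratio']}")
print("\nWith equal per-allele output both channels sit at the expected 2:1 "
      "per punctum; imposing 60% per-allele output on unpaired loci shifts "
      "the per-allele ratio to ~0.6 while the DNA channel stays at 2:1 — "
      "the dissociation that distinguishes transcriptional suppression from "
      "a labeling artifact.")
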