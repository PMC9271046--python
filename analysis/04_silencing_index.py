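#!/usr/bin/env python
"""Silencing-index recovery and the single-plane vs whole-cell validation.

Three experiments, all end-to-end from rendered images:
  1. equal mRNA rates in GSC and 2-4 SG  -> SI ~ 1 (no downregulation)
  2. two-fold rate decline               -> SI ~ 2
  3. mid-plane vs whole-cell scoring on a contamination-bearing scene:
     the two SIs should agree within ~10%

Writes: results/04_silencing_index.json
"""

import dataclasses
import json
from pathlib import Path

import pairfish as pf
from pairfish import validation as val

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

report = {}
for name, rate_sg in (("flat", 12.0), ("twofold_decline", 6.0)):
    scene = val.si_scene(seed=50, rate_gsc=12.0, rate_sg=rate_sg,
                         n_per_stage=150)
    si = val.measure_si(scene, seed=51)
    report[name] = dataclasses.asdict(si)
    del scene

scene = pf.generate_scene(pf.SceneConfig(
    n_cells_per_stage={"GSC": 60, "GB": 0, "SG2_4": 60, "SG8_16": 0,
                       "SC": 0, "CySC": 0}, seed=52))
v = pf.midplane_vs_wholecell_validation(scene, seed=53)
report["midplane_vs_wholecell"] = {
    "si_midplane": v["si_midplane"].si,
    "si_wholecell": v["si_wholecell"].si,
    "relative_difference": v["relative_difference"],
}

(OUT / "04_silencing_index.json").write_text(json.dumps(report, indent=2))
print(json.dumps({k: (round(v["si"], 3) if "si" in v else v)
                  for k, v in report.items()}, indent=2, default=str))
print("\nA flat expression profile reads out as SI ~ 1 and a two-fold "
      "decline as SI ~ 2; single-plane and whole-cell scoring agree, which "
      "is what licenses the cheaper mid-plane counting in the presence of "
      "somatic surface contamination.")
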