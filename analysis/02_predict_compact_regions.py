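#!/usr/bin/env python
"""Average-distance-map prediction of compact regions.

Planted ground truth: a 70-residue sequence whose statistics table makes
residues 5-25 and 40-60 short-distance blocks.  The map is built with
the generator's matched plot-density parameter D, scanned for density
differences, and the recovered regions with their compactness scores η
are written to results/adm_regions.tsv.
"""
import json
from pathlib import Path

from foldscan import adm, synthetic

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

spec = synthetic.PlantedSpec(length=70, seed=0, blocks=[(5, 25), (40, 60)])
sequence, table = synthetic.make_planted_stats(spec)
d = synthetic.planted_D(spec, table)
amap, profiles, regions = adm.analyze_sequence(sequence, table, D=d)

amap.to_edge_tsv(OUT / "adm_map_edges.tsv")
with open(OUT / "adm_regions.tsv", "w") as fh:
    fh.write("start\tend\teta\n")
    for r in regions:
        fh.write(f"{r.start}\t{r.end}\t{r.eta:.4f}\n")
with open(OUT / "adm_regions.json", "w") as fh:
    json.dump([r.as_dict() for r in regions], fh, indent=1)

print(f"planted blocks: {spec.blocks}; D = {d:.3f}; "
      f"map density {amap.density:.3f}")
for r in regions:
    print(f"recovered region {r.start}-{r.end}  eta = {r.eta:.3f}")
print(f"wrote {OUT / 'adm_regions.tsv'}")
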