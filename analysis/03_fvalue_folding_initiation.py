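#!/usr/bin/env python
"""F-value analysis: locate the folding-initiation residue of a chain
with a planted interaction hub.

A 30-mer whose central residue type has short statistical distances to
every other type is sampled in a random state (10 runs x 60,000 steps)
under the harmonic average-distance potential at the automatically
calibrated temperature; the z-scored contact frequencies are summed into
the per-residue F profile and its significant peaks are reported.
"""
from pathlib import Path

from foldscan import fvalue, synthetic

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

HUB = 15
spec = synthetic.PlantedSpec(length=30, seed=0, hub_position=HUB)
sequence, table = synthetic.make_planted_stats(spec)
profile = fvalue.analyze(sequence, table, n_runs=10, n_steps=60_000, seed=0)

with open(OUT / "fvalue_profile.tsv", "w") as fh:
    fh.write("residue\tF\n")
    for i, v in enumerate(profile.f, start=1):
        fh.write(f"{i}\t{v:.4f}\n")

print(f"calibrated sampling temperature kT = {profile.kT:.1f} "
      f"(acceptance target 0.5)")
print(f"F_cut = {profile.f_cut:.3f}")
for p in profile.peaks:
    mark = " <- planted hub" if abs(p["peak"] - HUB) <= 5 else ""
    print(f"peak at residue {p['peak']} "
          f"(window {p['window_start']}-{p['window_end']}){mark}")
print(f"wrote {OUT / 'fvalue_profile.tsv'}")
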