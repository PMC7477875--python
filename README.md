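# foldscan

Sequence-based prediction of protein folding-initiation sites, with a
structure-based simulation to check it against — built for β-trefoil
proteins (three-fold pseudo-symmetric all-β folds of ~130–210 residues,
including irregular members with insertions or missing strands), but
applicable to any single-domain protein.

The package answers three linked questions:

1. **Which parts of a sequence form compact regions early in folding?**
   An *average distance map* (ADM) is a contact map predicted from
   sequence alone: cell (i, j) is plotted when the statistical mean
   Cα–Cα distance for that residue-type pair at separation range
   M(|i−j|) falls below a per-range cutoff P(M)_c = (D/M)·P(M)_t, with
   D calibrated so the map density matches ρ_av = C/N (C = 36.12).
   Dense blocks on the diagonal, found by scanning density differences
   Δρ, are predicted compact regions scored by the compactness
   η = Δρ^h(start) + Δρ^v(end).

2. **Which residues are contact hubs in the unfolded state?** A Cα
   chain is Metropolis-sampled under harmonic restraints
   u_ij = (r − r̄_ij)²/2σ_ij² from the same distance statistics, at a
   temperature auto-calibrated to 50% acceptance. Contact counts
   g(i, j) are z-scored per range into Q(i, j), and peaks of
   F_i = Σ_j Q(i, j) above the noise floor F_cut (RMS of successive
   differences) mark putative folding-initiation residues.

3. **Does a structure-based model agree?** An orientation-dependent
   coarse-grained Gō model — native contacts from the heavy-atom
   vdW + 1.4 Å rule with strengths C_ij and an orientation factor
   B_ij(Θ_ij) built from bisector vectors h_i = r_{i,i−1} + r_{i,i+1} —
   is sampled by replica-exchange Monte Carlo (pivot + crankshaft
   moves); WHAM turns the multi-temperature (E, Q) records into free
   energy profiles F(Q; T), heat capacity C_v(T) and the folding
   temperature T_f, and contact-frequency maps at chosen Q show which
   contacts form in early folding.

A conservation toolkit (conserved hydrophobic residues at > 90%
hydrophobic alignment sites, > 70% region conservation, < 5 Å
hydrophobic packing, cross-protein occurrence matrices) ties the
sequence predictions to native-structure packing.

## Layout

```
src/foldscan/     library: stats, adm, fvalue, go_model, wham,
                  conservation, synthetic, pipeline, cli
analysis/         numbered driver scripts for the synthetic study
results/          tables the drivers write
scripts/          acceptance.py (see below)
docs/methods.md   models, parameters, numerical choices, limitations
```

## Worked example

Everything runs on synthetic data with planted ground truth (no
downloads). The numbered scripts under `analysis/` walk through the
whole study; for instance compact-region recovery:

```bash
$ python analysis/02_predict_compact_regions.py
planted blocks: [(5, 25), (40, 60)]; D = 0.036; map density 0.174
recovered region 5-25  eta = 0.896
recovered region 40-60  eta = 0.689
```

The two planted short-distance blocks come back exactly, the denser
N-terminal block with the higher compactness η. The F-value stage finds
a planted interaction hub:

```bash
$ python analysis/03_fvalue_folding_initiation.py
calibrated sampling temperature kT = 143.3 (acceptance target 0.5)
F_cut = 3.850
peak at residue 15 (window 10-20) <- planted hub
```

and the Gō-model stage folds and melts a 24-residue hairpin:

```bash
$ python analysis/05_go_folding_thermodynamics.py
hairpin: 24 residues, 19 native contacts
replica-exchange acceptance 0.55
T = 0.500: median Q = 0.95
T = 1.100: median Q = 0.00
transition temperature T_f = 0.681 (C_v peak)
```

Below T_f ≈ 0.68 the chain sits in the native basin (median fraction of
native contacts Q ≈ 0.95); above it, the chain is denatured (Q ≈ 0) —
the two-state picture the free-energy profiles in
`results/go_hairpin_free_energy.tsv` show as two wells.

The same operations are exposed as a CLI for real inputs (PDB files,
FASTA, alignments):

```bash
foldscan stats build --pdb-dir structures/ --min-count 10 --out stats.tsv
foldscan adm --fasta seq.fa --stats stats.tsv --out-prefix myprotein
foldscan fvalue --fasta seq.fa --stats stats.tsv --runs 10 --steps 60000 --seed 7
foldscan go prepare --pdb 1a8d.pdb --chain A --range 865:1069
foldscan go run --topology topology.json --tmin 0.84 --tmax 1.00 --ntemps 32
foldscan conserve chr --msa alignment.fa
foldscan run --config run.yaml         # config-driven pipeline
```

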