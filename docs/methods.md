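# Methods

foldscan implements a pipeline of sequence-based and structure-based
analyses of protein folding initiation, built around four components:
inter-residue average-distance statistics, the average distance map
(ADM), contact-frequency (F-value) sampling, and an
orientation-dependent coarse-grained Gō model with replica-exchange
Monte Carlo and WHAM. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data validation
does and does not establish.

## Inter-residue average-distance statistics

For every pair of amino-acid types (A, B) and every sequence-separation
range M — M = 1 for separations 1–8, M = 2 for 9–20, M = 3 for 21–30 and
decade-wide bins thereafter — the mean and population standard deviation
of the Cα–Cα distance are pooled over all residue pairs of a corpus of
folded structures. Separations beyond range `m_max` (default 20,
covering separations up to 200) pool into the last bin so that very long
chains do not create starved bins.

"Statistically significant" entries are operationalized as `count ≥
min_count` (default 10, configurable): entries with fewer observations
are dropped. Residue typing covers the 20 standard amino acids by
three-letter PDB name, with a small editable remapping table for common
nonstandard residues (MSE→MET, …); anything else is skipped with a
warning. Tables serialize as plain TSV (`A B M mean sd count`), so they
are diffable and versionable.

## Average distance map (ADM)

The ADM is a contact map predicted from sequence alone. Cell (i, j),
i < j, is plotted when the stored mean distance for (type_i, type_j,
M(|i−j|)) does not exceed a per-range cutoff. Cutoffs derive from the
counting rule P(M)_c = (D/M)·P(M)_t: with P_t significant pair types in
range M, the cutoff is the ⌈P_c⌉-th smallest of their means (capped at
P_t), so exactly that many pair types plot. The one free parameter D is
calibrated by bisection so the map density matches the empirical density
ρ_av = C/N of real contact maps at a 15 Å cutoff, with C = 36.12.
Density is a monotone step function of D; the bisection returns the step
closest to the target and warns if it misses by more than the tolerance
(default 0.005).

Compact regions are read off density-difference profiles. With cells
(a, b), a < b, and a 1-based residue index i:

- vertical scan: Δρ_i^v = ρ({a < b ≤ i}) − ρ({a ≤ i < b})
- horizontal scan: Δρ_i^h = ρ({i ≤ a < b}) − ρ({a < i ≤ b})

A line at the map edge does not divide the map, so Δρ_i = 0 when either
part has zero area. A compact block [m, n] makes Δρ^h peak at m (the
start) and Δρ^v peak at n (the end); a region is a (start, end) pair
scored by the compactness η = Δρ^h(start) + Δρ^v(end).

Peak detection: candidates are local maxima of the 3-point-smoothed
profiles, snapped to the raw-profile maximum and validated by a
*one-sided* prominence — a start by how far Δρ^h falls over the
following `min_length` residues, an end by how far Δρ^v rose over the
preceding `min_length`. The one-sided rule is deliberate: for a region
at the chain terminus the outer boundary peak is flattened by the
shrinking map edge (the triangle on its outer side contains almost the
whole map), so a symmetric prominence criterion silently discards
exactly the terminal regions the analysis cares about. The validation
threshold is 0.5 profile standard deviations; the minimum region length
is 10 residues. Starts pair with the nearest subsequent end; overlaps
resolve in favour of higher η, except near-ties within 0.003, which are
both kept (region pairs whose η differ by so little are scientifically
indistinguishable). All coordinates are 1-based inclusive.

## Contact-frequency (F-value) analysis

A Cα virtual-bond chain (bond length fixed at 3.8 Å) is sampled in a
random state — no secondary or tertiary structure, no excluded volume —
under pairwise harmonic restraints derived from the statistics table:

    u_ij(r) = (r − r̄_ij)² / (2 σ_ij²)

per residue pair with a stored (r̄, σ) entry; pairs without statistics,
or with σ = 0, contribute nothing. One MC step perturbs every bond angle
(reflected into (0, π)) and dihedral (wrapped) by uniform(−δ, δ),
δ = 10° by default, rebuilds the chain and applies a single Metropolis
accept/reject with the factor exp(−ΔU/τ).

On the energy scale: the restraint energy is defined only up to the
temperature used in its derivation, so the dimensionless form above is
taken as the potential and the sampling temperature τ (written kT
throughout the interfaces) is the free parameter. It is calibrated by
bisection on log τ until a probe run's acceptance ratio is 0.5 ± 0.02
— the operating point at which the sampler neither freezes into the
restraint minima nor ignores them. Calibration is validated on an
independent run with a fresh seed. Any fixed prefactor on U would be
absorbed into τ by the calibration, which is why the calibration is
meaningful at all.

Contacts (distance < 15 Å, the same cutoff that defines real-distance
contact maps; a free parameter, configurable) are counted for the
current structure at every step of every run, the initial random
conformation included, over 10 runs × 60,000 steps by default. Counts
g(i, j) are z-scored within each separation range M (population standard
deviation D(M); ranges with D(M) = 0 give Q = 0), and the F profile is
the row sum F_i = Σ_j Q(i, j). Peaks count as real when they rise above
both flanking valleys (chain ends count as valleys) by more than F_cut,
the RMS of successive F differences; a window of ±5 residues around a
peak is reported as the folding-significant neighbourhood.

## Orientation-dependent Gō model

The energy of a conformation, in units of the contact energy ε:

    E = Σ K_θ (θ_i − θ_i0)²
      + Σ { K_φ¹ [1 − cos(φ_i − φ_i0)] + K_φ³ [1 − cos 3(φ_i − φ_i0)] }
      + Σ_NC ε C_ij [ 5 (r_ij0/r_ij)¹² − B_ij 6 (r_ij0/r_ij)¹⁰ ]
      + Σ_NNC (4 Å / r_ij)¹²

with K_θ = 20ε, K_φ¹ = ε, K_φ³ = 0.5ε. The dihedral wells carry constant
offsets (the "1 −" terms) so that every local term vanishes at the
native state; offsets cancel in all energy differences. A native
contact exists between residues with |i−j| ≥ 4 when any heavy-atom pair
sits within the sum of the two Bondi van der Waals radii + 1.4 Å; C_ij
is the number of such atom pairs normalized to mean 1 over contacts.
Every |i−j| ≥ 4 pair not in the contact set feels the (4 Å/r)¹²
repulsion. Consequently the native-state energy decomposes into exactly
−Σ εC_ij from the native term plus a small positive non-native steric
background; `go_energy_terms` exposes the decomposition.

The orientation factor compares the angle Θ_ij between the
side-chain-mimicking bisector vectors h_i = r_{i,i−1} + r_{i,i+1} with
its native value: B_ij = 1 − (Θ_ij − Θ_ij0)²/a_Θ² for |ΔΘ| < a_Θ = 0.6π,
else 0. Terminal residues have no h, so B = 1 there. Bond angles are
kept strictly below π (proposals reaching θ ≥ π − 10⁻⁹ are rejected) so
h never vanishes; starting conformations are validated for the same
condition.

Sampling: one MC step is N pivot moves (a random arm rotated about a
random axis through a random residue, angle uniform in (−π, π)) followed
by N crankshaft moves (a random interior segment of length ≤ N/2 rotated
about its end-to-end axis), each with its own Metropolis judgment.
ΔE per move is computed incrementally from the boundary-crossing terms
of the rotated rigid segment — distances within the segment and outside
it are unchanged, and the bisector vectors of the segment's strict
interior rotate rigidly, so only contacts crossing the boundary or
touching the four boundary-adjacent residues need re-evaluation. The
running total is resynchronized against a full recomputation every 100
exchange blocks; tests verify the incremental and full energies agree to
10⁻⁶ (observed drift ~10⁻¹¹ over 10⁵ moves).

Replica exchange runs one replica per ladder temperature (geometric
ladder by default), attempting swaps of alternating even/odd adjacent
pairs every 100 steps with acceptance min(1, exp[(β_a − β_b)(E_a −
E_b)]). Replicas start from the native conformation; the equilibration
phase (discarded) lets the hot replicas melt, and exchange carries
unfolded configurations down the ladder, so both basins are sampled
where they are thermodynamically relevant. (E, Q) and the per-contact
formation states are recorded every 10 steps. A contact is "formed" when
r < 1.2·r_ij0 (configurable); Q is the formed fraction of native
contacts. Identical seeds give bit-identical trajectories: per-block
kernel seeds derive from the master seed via SeedSequence.

## WHAM

Free energies come from self-consistent WHAM on 2-D (E, Q) histograms
(50 × 40 bins by default), iterated until the window free energies
change by less than 10⁻⁷, all sums in log space. Outputs: F(Q; T) at
requested temperatures (reported with minimum 0), the heat capacity
C_v(T) = (⟨E²⟩ − ⟨E⟩²)/T² on a fine grid from the estimated density of
states, and the transition temperature T_f at the C_v peak. With a
single temperature the equations reduce exactly to the direct histogram
(tested to 10⁻⁶); non-overlapping neighbouring energy histograms raise
an error naming the offending temperatures.

## Conservation analyses

Hydrophobic residues are Ala, Phe, Ile, Leu, Met, Val, Tyr, Trp. A
conserved hydrophobic residue (CHR) is an alignment site whose
hydrophobic fraction strictly exceeds 90%, with gaps counted in the
denominator (a gapped sequence cannot contribute a hydrophobic residue
at the site). Region conservation is the per-site fraction of proteins
whose predicted compact regions cover the site, mapped through each
sequence's gap structure; maximal runs strictly above 70% are the
conserved spans. Hydrophobic packing between two residues means closest
heavy atoms strictly under 5 Å with sequence separation > 3. Occurrence
matrices report, per labelled CHR pair, the percentage of proteins
showing the packing contact; a protein missing either CHR (e.g. a
protein whose fold lacks that strand) is excluded from that cell's
denominator. Cells at 100% and ≥ 95% are flagged. Strand labels (β1,
β2N, β2C, …) come from a user-supplied annotation of alignment-coordinate
intervals, since secondary-structure assignment is outside this
package's scope.

## Synthetic data and what the tests show

The generators provide every input class with planted ground truth:

- **Corpora**: collapsed self-avoiding Cα chains (3.8 Å bonds, 4 Å
  excluded volume, growth biased toward the centroid) with random
  sequences, for statistics building. They are compact (median R_g <
  3·N^⅓ Å) but have no secondary structure, no hydrophobic core, no
  sequence–structure correlation.
- **Planted statistics tables**: block residue types with short
  same-type means (6 Å) versus a long background (20 Å ± 25% per-pair
  jitter, σ = 2 Å), and optionally a hub type with short means to every
  type. The jitter makes the per-range cutoffs resolve gradually. The
  matched plot-density parameter for these bimodal tables is supplied by
  the generator (`planted_D`); the C/N calibration is meant for real
  corpus tables whose means vary continuously.
- **Mini natives**: an idealized 24-residue two-strand hairpin and a
  56-residue three-hairpin arrangement around a pseudo three-fold axis
  (a topological stand-in for a three-unit β-barrel-and-cap fold), each
  with one pseudo side-chain atom per residue placed 1.5 Å along the
  −h bisector so the heavy-atom contact rule and C_ij are nontrivial.
  Linkers zigzag slightly so no bond-angle is exactly π.
- **Alignments**: planted 100%-hydrophobic columns over a 30%
  hydrophobic background, and per-protein region lists covering given
  spans in 90% of sequences.

Passing the recovery tests therefore shows that the machinery is
correct — the statistics, map construction, scanning, normalization,
sampling and thermodynamics do what their formulas say, with known
ground truth recovered at high power. It does not show that the
method's predictions are accurate on real proteins: the synthetic
conditions are cleanly separable by construction, while real statistics
tables are noisy and real compact regions are not rectangular blocks.

## Problem sizes

The default validation runs are sized for a single CPU: block recovery
at N = 70 (10 seeds, seconds), hub recovery at N = 30 with 10 × 60,000
steps (~30 s), hairpin thermodynamics with 8 temperatures × (2·10⁴ +
2·10⁵) steps (~7 min), and the trefoil-toy protocol with 6 temperatures
× 1.5·10⁴ steps (~90 s). The full-protein protocol (32 temperatures,
10⁵ + 10⁶ steps, ~200 residues) runs through the same code path via the
CLI but takes days of CPU and needs externally supplied PDB structures
and a structure-based alignment.

## Known limitations

- The published region boundaries and η values for the β-trefoil toxins
  are not reproducible here: they depend on a specific unpublished
  statistics corpus. This package builds its own tables from any corpus.
- The F-value sampler has no excluded volume; its ensembles are
  restraint-shaped random coils, by design.
- The contact-counting cutoff (15 Å) and the per-step angle perturbation
  (10°) are declared parameters; the analyses' variance with respect to
  them has not been mapped.
- WHAM heat capacities inherit histogram-binning bias; the two-state-toy
  test bounds it at the 2% level for the default binning.
- The Cα-only contact fallback (contact iff Cα distance < 6.5 Å,
  C_ij ≡ 1) exists for structures without heavy atoms and is flagged in
  the topology metadata; it is not equivalent to the heavy-atom rule.
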