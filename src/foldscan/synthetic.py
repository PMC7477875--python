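"""Synthetic data: structure corpora, planted statistics, mini Gō targets
and alignments with known ground truth.

These generators define the study conditions for every statistical test
in the package: compact Cα chains for building distance statistics,
statistics tables with planted short-distance "blocks" (average-distance-map
recovery) and a planted "hub" residue type (F-value peak recovery),
idealized mini β-structures with pseudo side-chain atoms (Gō topology),
and alignments with planted conserved hydrophobic columns.  Everything
is seed-deterministic and emitted in the standard formats the analysis
modules read.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import DEFAULT_M_MAX, N_AA, DistanceStatistics
from .structure import (AA1_TO_3, AA3_TO_1, AA_INDEX, STANDARD_AA,
                        CaStructure, Residue)

BOND = 3.8
EXCLUDED = 4.0


@dataclass
class PlantedSpec:
    """Ground-truth carrier for parameter-recovery tests."""

    length: int
    seed: int
    blocks: list[tuple[int, int]] = field(default_factory=list)   # 1-based inclusive
    hub_position: int | None = None
    short_mean: float = 6.0
    long_mean: float = 20.0
    sigma: float = 2.0

    def __post_init__(self) -> None:
        for (a, b) in self.blocks:
            if not (1 <= a < b <= self.length):
                raise ValueError(f"block ({a}, {b}) outside [1, {self.length}]")
        if self.hub_position is not None and not (1 <= self.hub_position <= self.length):
            raise ValueError("hub position outside sequence")


# ---------------------------------------------------------------------------
# compact chain corpus
# ---------------------------------------------------------------------------

def _grow_compact_chain(n: int, rng: np.random.Generator,
                        n_candidates: int = 30, max_restarts: int = 200) -> np.ndarray:
    """Chain growth: 3.8 Å bonds, 4 Å excluded volume, bias to the centroid.

    Each bead picks, among random directions that respect excluded
    volume, the one closest to the running centroid (with a little
    noise), yielding collapsed globule-like chains.
    """
    for _ in range(max_restarts):
        x = np.zeros((n, 3))
        x[1] = (BOND, 0.0, 0.0)
        ok = True
        for i in range(2, n):
            centroid = x[:i].mean(axis=0)
            dirs = rng.standard_normal((n_candidates, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            cand = x[i - 1] + BOND * dirs
            d = np.linalg.norm(cand[:, None, :] - x[None, :i - 1, :], axis=2)
            valid = (d >= EXCLUDED).all(axis=1)
            if not valid.any():
                ok = False
                break
            cand = cand[valid]
            score = np.linalg.norm(cand - centroid, axis=1)
            score = score + rng.normal(0.0, 1.0, size=len(score))
            x[i] = cand[np.argmin(score)]
        if ok:
            return x
    raise RuntimeError("compact chain growth failed repeatedly")


def make_corpus(n_structures: int, length: int, seed: int) -> list[CaStructure]:
    """Compact self-avoiding Cα chains with random sequences."""
    if n_structures < 1:
        raise ValueError("need at least one structure")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    corpus = []
    for s in range(n_structures):
        coords = _grow_compact_chain(length, rng)
        names = [STANDARD_AA[t] for t in rng.integers(0, N_AA, size=length)]
        corpus.append(CaStructure(
            [Residue(nm, c) for nm, c in zip(names, coords)],
            name=f"synth{s:03d}", synthetic=False))
    return corpus


# ---------------------------------------------------------------------------
# planted statistics tables
# ---------------------------------------------------------------------------

#: Residue types reserved for planted roles; background uses the rest.
BLOCK_TYPES = ("LEU", "VAL")
HUB_TYPE = "TRP"
BACKGROUND_TYPES = ("GLY", "SER", "GLU", "LYS", "ASP", "THR", "ASN", "GLN")


def make_planted_stats(spec: PlantedSpec,
                       m_max: int = DEFAULT_M_MAX) -> tuple[str, DistanceStatistics]:
    """A sequence plus a statistics table with known compact ground truth.

    Residues inside each planted block get a dedicated block type whose
    same-type mean distance is short (``short_mean``); the hub position
    gets a type whose mean to *every* type is short.  All other pair
    means are long.  Short vs long separated by ≫ σ makes recovery
    essentially deterministic at desk scale.
    """
    if spec.hub_position is not None:
        hub_1based = spec.hub_position
        for (a, b) in spec.blocks:
            if a <= hub_1based <= b:
                raise ValueError("hub position inside a planted block: "
                                 "roles would contradict each other")
    if len(spec.blocks) > len(BLOCK_TYPES):
        raise ValueError(f"at most {len(BLOCK_TYPES)} planted blocks supported")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    bg = [AA_INDEX[t] for t in BACKGROUND_TYPES]
    seq_types = np.array(rng.choice(bg, size=spec.length))
    for bidx, (a, b) in enumerate(spec.blocks):
        seq_types[a - 1:b] = AA_INDEX[BLOCK_TYPES[bidx]]
    if spec.hub_position is not None:
        seq_types[spec.hub_position - 1] = AA_INDEX[HUB_TYPE]
    sequence = "".join(AA3_TO_1[STANDARD_AA[t]] for t in seq_types)
    mean = np.full((N_AA, N_AA, m_max + 1), np.nan)
    sd = np.zeros((N_AA, N_AA, m_max + 1))
    count = np.zeros((N_AA, N_AA, m_max + 1), dtype=np.int64)
    used = sorted(set(seq_types.tolist()))
    hub = AA_INDEX[HUB_TYPE]
    block_idx = [AA_INDEX[t] for t in BLOCK_TYPES]
    # background means get a per-(A,B,M) spread around long_mean so the
    # per-range cutoffs resolve gradually instead of in one giant step
    for m in range(1, m_max + 1):
        for a in used:
            for b in used:
                if b < a:
                    continue
                if a == b and a in block_idx:
                    mu = spec.short_mean
                elif hub in (a, b) and spec.hub_position is not None:
                    mu = spec.short_mean
                else:
                    mu = spec.long_mean + rng.uniform(-0.25, 0.25) * spec.long_mean
                mean[a, b, m] = mean[b, a, m] = mu
                sd[a, b, m] = sd[b, a, m] = spec.sigma
                count[a, b, m] = count[b, a, m] = 100
    return sequence, DistanceStatistics(mean, sd, count, m_max=m_max,
                                        corpus_id=f"planted(seed={spec.seed})",
                                        min_count=1)


def planted_D(spec: PlantedSpec, table: DistanceStatistics) -> float:
    """The plot-density parameter D matching a planted table's design.

    The planted tables are bimodal (short vs long means), so the map the
    plant encodes is the one whose per-range cutoffs fall between the two
    modes.  With n_short short entries among P_t significant entries in
    range 1, D = n_short/P_t makes range 1 plot exactly the short pair
    types and every higher range at most those (ceil(n_short/M) of them),
    all of which share the short mean.  This is the generator fixing its
    own study conditions; the empirical C/N calibration applies to real
    corpus statistics, whose means vary continuously.
    """
    thr = 0.5 * (spec.short_mean + spec.long_mean)
    iu = np.triu_indices(N_AA)
    means = table.mean[iu[0], iu[1], 1]
    means = means[~np.isnan(means)]
    p_t = len(means)
    n_short = int((means < thr).sum())
    if n_short == 0 or p_t == 0:
        raise ValueError("table has no planted short entries")
    return n_short / p_t


# ---------------------------------------------------------------------------
# mini native structures
# ---------------------------------------------------------------------------

def _pseudo_sidechains(coords: np.ndarray) -> list[list[tuple[str, np.ndarray]]]:
    """One pseudo side-chain atom per residue, 1.5 Å along the −h bisector.

    h_i = r_{i,i−1} + r_{i,i+1} points between the neighbours; placing
    the pseudo atom opposite it mimics a Cβ and makes the heavy-atom
    contact rule (and C_ij) nontrivial on synthetic structures.
    """
    n = len(coords)
    atoms: list[list[tuple[str, np.ndarray]]] = []
    for i in range(n):
        entry = [("C", coords[i])]           # the Cα itself
        if 0 < i < n - 1:
            h = (coords[i - 1] - coords[i]) + (coords[i + 1] - coords[i])
            nh = np.linalg.norm(h)
            if nh > 1e-9:
                entry.append(("C", coords[i] - 1.5 * h / nh))
        atoms.append(entry)
    return atoms


def _hairpin_coords(n: int, strand_sep: float = 5.0,
                    rise: float = 3.3, zig: float = 0.9) -> np.ndarray:
    """Idealized two-strand antiparallel hairpin, ~3.45 Å virtual bonds."""
    n_turn = 2
    n_strand = (n - n_turn) // 2
    extra = n - n_turn - 2 * n_strand
    coords = []
    for i in range(n_strand):                       # strand 1: +z
        coords.append((zig * (-1) ** i, 0.0, i * rise))
    top = (n_strand - 1) * rise
    # turn: two beads arcing over to the second strand (bonds ~3.3-3.7 Å)
    coords.append((strand_sep / 2 - 1.75, 2.0, top + 2.6))
    coords.append((strand_sep / 2 + 1.75, 2.0, top + 2.6))
    for i in range(n_strand + extra):               # strand 2: −z
        coords.append((strand_sep + zig * (-1) ** i, 0.0, top - i * rise))
    return np.asarray(coords)


def _trefoil_toy_coords(n_unit: int = 16, link: int = 2) -> np.ndarray:
    """Three hairpins around a pseudo three-fold axis, hairpin linkers.

    A desk-scale topological mimic of the β-trefoil's three-unit
    barrel-and-cap schematic; geometry is idealized, not physical.
    """
    hp = _hairpin_coords(n_unit)
    hp = hp - hp.mean(axis=0)
    radius = 9.0
    units = []
    for k in range(3):
        ang = 2 * np.pi * k / 3
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0],
                        [0, 0, 1.0]])
        center = radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        units.append(hp @ rot.T + center)
    coords = [units[0]]
    for k in range(1, 3):
        prev_end = coords[-1][-1]
        nxt = units[k]
        gap = nxt[0] - prev_end
        d = np.linalg.norm(gap)
        n_link = max(link, int(round(d / 3.5)) - 1)
        # alternate a lateral offset so no three beads are collinear
        # (collinear triples make the bisector vector h vanish)
        perp = np.cross(gap, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        ts = [(i + 1) / (n_link + 1) for i in range(n_link)]
        bridge = np.asarray([prev_end + t * gap + 0.6 * (-1) ** i * perp
                             for i, t in enumerate(ts)])
        coords.append(bridge)
        coords.append(nxt)
    return np.vstack(coords)


def make_mini_native(kind: str, n_residues: int = 24, seed: int = 0) -> CaStructure:
    """Deterministic idealized mini structure with pseudo heavy atoms.

    ``kind``: "hairpin" (two antiparallel strands) or
    "three_hairpin_trefoil_toy" (barrel-and-cap-like arrangement of three
    hairpins; ``n_residues`` is ignored beyond a ≤ 60 sanity cap).
    """
    if n_residues > 60:
        raise ValueError("mini natives are capped at 60 residues")
    if kind == "hairpin":
        coords = _hairpin_coords(n_residues)
    elif kind == "three_hairpin_trefoil_toy":
        coords = _trefoil_toy_coords()
        if len(coords) > 60:
            coords = coords[:60]
    else:
        raise ValueError(f"unknown mini-native kind: {kind}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    hydro = [AA1_TO_3[c] for c in "AFILMVYW"]
    names = [hydro[t] for t in rng.integers(0, len(hydro), size=len(coords))]
    atoms = _pseudo_sidechains(coords)
    residues = [Residue(nm, c, heavy_atoms=at)
                for nm, c, at in zip(names, coords, atoms)]
    return CaStructure(residues, name=f"mini-{kind}", synthetic=True)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

HYDROPHOBIC_1 = "AFILMVYW"
POLAR_1 = "DEGKNQRSTH"


def make_msa(n_seq: int, length: int, chr_columns=(), region_spans=(),
             seed: int = 0, background_hydrophobic: float = 0.3,
             region_coverage: float = 0.9):
    """Random alignment with planted CHR columns and region lists.

    Planted columns are 100% hydrophobic (recovered by the > 90% rule);
    elsewhere hydrophobic residues appear at the background rate.
    ``region_spans`` (alignment coordinates) are covered by the predicted
    regions of a ``region_coverage`` fraction of the sequences, so the
    70% conservation rule has known ground truth.  Returns
    (msa as list of (id, seq), regions_per_protein dict).
    """
    for c in chr_columns:
        if not (1 <= c <= length):
            raise ValueError(f"CHR column {c} outside [1, {length}]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    msa = []
    regions: dict[str, list[tuple[int, int]]] = {}
    chr_set = set(chr_columns)
    n_regioned = int(round(region_coverage * n_seq))
    for s in range(n_seq):
        chars = []
        for pos in range(1, length + 1):
            if pos in chr_set:
                chars.append(HYDROPHOBIC_1[rng.integers(len(HYDROPHOBIC_1))])
            elif rng.random() < background_hydrophobic:
                chars.append(HYDROPHOBIC_1[rng.integers(len(HYDROPHOBIC_1))])
            else:
                chars.append(POLAR_1[rng.integers(len(POLAR_1))])
        sid = f"seq{s:03d}"
        msa.append((sid, "".join(chars)))
        # no gaps planted: alignment coordinate == residue coordinate
        if s < n_regioned:
            regions[sid] = [(a, b) for a, b in region_spans]
        else:
            regions[sid] = []
    return msa, regions


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")
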