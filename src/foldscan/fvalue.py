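"""Contact-frequency (F-value) analysis.

A Cα virtual-bond chain is sampled in a "random state" — no secondary or
tertiary structure, only the statistical restraints — under a harmonic
potential whose minimum for each residue pair sits at the corpus mean
distance r̄ with width σ (per residue-type pair and separation range M):

    u_ij(r) = (r − r̄_ij)² / (2 σ_ij²)

Metropolis sampling at a dimensionless temperature τ (calibrated so the
acceptance ratio is 0.5) yields contact counts g(i, j); z-scoring g
within each range M gives Q(i, j), and the per-residue sums
F_i = Σ_j Q(i, j) locate putative folding-initiation residues at their
peaks.  Peaks count as real when they rise above both flanking valleys
by more than F_cut, the RMS of successive F differences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .stats import DistanceStatistics, _ranges_for_length
from .structure import AA1_TO_3, AA_INDEX

log = logging.getLogger(__name__)

#: Virtual Cα–Cα bond length, Å.
BOND_LENGTH = 3.8
#: Contact-counting cutoff for g(i, j), Å.  The value of the real-distance-map
#: cutoff; a free parameter of this analysis, not fitted to anything.
DEFAULT_CONTACT_CUTOFF = 15.0
#: Per-step angle perturbation half-width (radians); ~10°.
DEFAULT_DELTA = np.deg2rad(10.0)


@dataclass
class HarmonicPotential:
    """Pairwise harmonic restraints r̄/σ mapped onto one sequence."""

    sequence: str
    rbar: np.ndarray          # (N, N) mean distances, 0 where absent
    half_weight: np.ndarray   # (N, N) 1/(2σ²), 0 where excluded
    kT: float = 1.0

    @property
    def n(self) -> int:
        return len(self.sequence)

    def energy(self, coords: np.ndarray) -> float:
        """ε(Γ) = kT · Σ u_ij  (kT is the reported energy scale)."""
        return self.kT * _kernels.harmonic_energy(
            np.ascontiguousarray(coords, dtype=float), self.rbar, self.half_weight)

    def reduced_energy(self, coords: np.ndarray) -> float:
        return _kernels.harmonic_energy(
            np.ascontiguousarray(coords, dtype=float), self.rbar, self.half_weight)


def build_potential(sequence: str, stats: DistanceStatistics,
                    kT: float = 1.0) -> HarmonicPotential:
    """Harmonic potential for one sequence from a statistics table.

    Pairs with no stored statistics, or with σ = 0, contribute no energy
    (σ = 0 entries are excluded with a warning — a zero-width restraint
    is a rigid constraint, not a statistical one).
    """
    n = len(sequence)
    types = np.array([AA_INDEX[AA1_TO_3[c]] for c in sequence])
    mlab = _ranges_for_length(n, stats.m_max)
    ii, jj = np.triu_indices(n, k=1)
    m = mlab[jj - ii]
    mean = stats.mean[types[ii], types[jj], m]
    sd = stats.sd[types[ii], types[jj], m]
    have = ~np.isnan(mean)
    zero_sd = have & (sd <= 0)
    if zero_sd.any():
        log.warning("excluding %d zero-sigma pair entries from the potential",
                    int(zero_sd.sum()))
    usable = have & (sd > 0)
    rbar = np.zeros((n, n))
    hw = np.zeros((n, n))
    rbar[ii[usable], jj[usable]] = mean[usable]
    hw[ii[usable], jj[usable]] = 1.0 / (2.0 * sd[usable] ** 2)
    return HarmonicPotential(sequence, rbar, hw, kT=kT)


def _seed_for(seed: int, *branch: int) -> int:
    ss = np.random.SeedSequence([seed, *branch])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def measure_acceptance(potential: HarmonicPotential, kT: float,
                       n_steps: int, seed: int,
                       delta: float = DEFAULT_DELTA) -> float:
    """Metropolis acceptance fraction of an ``n_steps`` probe run at kT."""
    _, acc, _ = _kernels.fvalue_mc(potential.rbar, potential.half_weight,
                                   n_steps, kT, delta, DEFAULT_CONTACT_CUTOFF,
                                   _seed_for(seed, 0), False)
    return acc


def calibrate_kT(potential: HarmonicPotential, probe_steps: int = 5000,
                 seed: int = 0, target: float = 0.5, tol: float = 0.02,
                 delta: float = DEFAULT_DELTA, max_iter: int = 40) -> float:
    """Bisection on log kT until the probe acceptance ratio hits 0.5.

    Acceptance increases monotonically with kT (up to sampling noise):
    kT → ∞ accepts everything, kT → 0 accepts only downhill proposals.
    """
    if probe_steps < 1000:
        raise ValueError("probe_steps must be >= 1000 for a stable estimate")
    lo, hi = 1e-3, 1e3
    curve = []
    acc_lo = measure_acceptance(potential, lo, probe_steps, seed, delta)
    curve.append((lo, acc_lo))
    while acc_lo >= target and lo > 1e-12:
        lo *= 1e-3
        acc_lo = measure_acceptance(potential, lo, probe_steps, seed, delta)
        curve.append((lo, acc_lo))
    acc_hi = measure_acceptance(potential, hi, probe_steps, seed, delta)
    curve.append((hi, acc_hi))
    while acc_hi <= target and hi < 1e12:
        hi *= 1e3
        acc_hi = measure_acceptance(potential, hi, probe_steps, seed, delta)
        curve.append((hi, acc_hi))
    if not (acc_lo < target < acc_hi):
        raise RuntimeError(
            f"cannot bracket acceptance {target}: {curve}; "
            "potential may be degenerate (all-downhill or flat)")
    kt = np.sqrt(lo * hi)
    for it in range(max_iter):
        kt = np.sqrt(lo * hi)
        acc = measure_acceptance(potential, kt, probe_steps, seed + it + 1, delta)
        if abs(acc - target) <= tol:
            return float(kt)
        if acc < target:
            lo = kt
        else:
            hi = kt
    return float(kt)


def sample_chain(potential: HarmonicPotential, kT: float,
                 n_runs: int = 10, n_steps: int = 60000,
                 contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                 seed: int = 0, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """Accumulate contact counts g(i, j) over independent Metropolis runs.

    Each run starts from random bond/dihedral angles; every step perturbs
    all angles, applies one accept/reject, and counts the current
    structure's contacts (the initial conformation included).  There is
    no excluded-volume term in this sampler — the restraints alone shape
    the ensemble.
    """
    n = potential.n
    g = np.zeros((n, n), dtype=np.int64)
    for run in range(n_runs):
        gr, _, _ = _kernels.fvalue_mc(potential.rbar, potential.half_weight,
                                      n_steps, kT, delta, contact_cutoff,
                                      _seed_for(seed, 1, run), True)
        g += gr
    return g + g.T


def normalize_contacts(g: np.ndarray, m_max: int = 20) -> np.ndarray:
    """Z-score g(i, j) within each separation range M (Q(i, j)).

    D(M) is the population standard deviation of g over pairs in range M;
    ranges with D(M) = 0 give Q = 0.
    """
    n = g.shape[0]
    mlab = _ranges_for_length(n, m_max)
    ii, jj = np.triu_indices(n, k=1)
    m = mlab[jj - ii]
    vals = g[ii, jj].astype(float)
    q = np.zeros((n, n))
    for mm in np.unique(m):
        sel = m == mm
        mu = vals[sel].mean()
        d = vals[sel].std()
        z = (vals[sel] - mu) / d if d > 0 else np.zeros(sel.sum())
        q[ii[sel], jj[sel]] = z
    return q + q.T


def f_profile(q: np.ndarray) -> np.ndarray:
    """F_i = Σ_j Q(i, j)."""
    return q.sum(axis=1)


def f_cut(f: np.ndarray) -> float:
    """RMS of successive F differences: the peak-prominence floor."""
    d = np.diff(f)
    return float(np.sqrt(np.mean(d * d)))


def detect_peaks(f: np.ndarray, window: int = 5) -> tuple[float, list[dict]]:
    """Real peaks of an F profile: local maxima more than F_cut above
    both flanking valleys.  Each peak is reported with its ± ``window``
    residue folding-significant window (1-based)."""
    n = len(f)
    if n < 3:
        raise ValueError("profile too short")
    fc = f_cut(f)
    peaks = []
    for i in range(1, n - 1):
        if not (f[i] > f[i - 1] and f[i] >= f[i + 1]):
            continue
        left = f[:i]
        right = f[i + 1:]
        # nearest valley on each side (chain ends count as valleys)
        lv = f[i - 1]
        for k in range(i - 1, 0, -1):
            if f[k] <= f[k - 1] and f[k] <= f[k + 1]:
                lv = f[k]
                break
        else:
            lv = f[0]
        rv = f[i + 1]
        for k in range(i + 1, n - 1):
            if f[k] <= f[k - 1] and f[k] <= f[k + 1]:
                rv = f[k]
                break
        else:
            rv = f[n - 1]
        if (f[i] - lv) > fc and (f[i] - rv) > fc:
            peaks.append({"peak": i + 1,
                          "window_start": max(1, i + 1 - window),
                          "window_end": min(n, i + 1 + window)})
    return fc, peaks


@dataclass
class FValueProfile:
    """Everything the F-value analysis produces for one sequence."""

    sequence: str
    g_matrix: np.ndarray
    q_matrix: np.ndarray
    f: np.ndarray
    f_cut: float
    peaks: list[dict] = field(default_factory=list)
    kT: float = 1.0


def analyze(sequence: str, stats: DistanceStatistics,
            n_runs: int = 10, n_steps: int = 60000,
            contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
            seed: int = 0, kT: float | None = None,
            probe_steps: int = 5000) -> FValueProfile:
    """Full F-value pass: calibrate kT (unless given), sample, normalize."""
    pot = build_potential(sequence, stats)
    if kT is None:
        kT = calibrate_kT(pot, probe_steps=probe_steps, seed=seed)
    g = sample_chain(pot, kT, n_runs=n_runs, n_steps=n_steps,
                     contact_cutoff=contact_cutoff, seed=seed)
    q = normalize_contacts(g, m_max=stats.m_max)
    f = f_profile(q)
    fc, peaks = detect_peaks(f)
    return FValueProfile(sequence, g, q, f, fc, peaks, kT=kT)
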