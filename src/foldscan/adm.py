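"""Average distance map (ADM) construction and compact-region prediction.

An ADM is a contact map predicted from sequence alone: cell (i, j) is
plotted when the statistical mean Cα–Cα distance for the residue-type
pair at the separation range M = M(|i−j|) falls below a per-range cutoff.
Cutoffs are set so that range M plots its fraction (D/M) of the
statistically significant pair types, and the overall plot density is
calibrated to the empirical density ρ_av = C/N of real 15 Å contact maps
(C = 36.12).

Compact regions show up as dense blocks hugging the diagonal.  They are
located by scanning density differences Δρ between the two parts the map
is cut into by a vertical or horizontal line at each residue; a region
runs from a horizontal-scan peak (start) to a vertical-scan peak (end)
and is scored by the compactness η = Δρ^h(start) + Δρ^v(end).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .stats import DistanceStatistics, _ranges_for_length
from .structure import AA1_TO_3, AA_INDEX

log = logging.getLogger(__name__)

#: Empirical density constant: a real contact map at 15 Å has density ≈ C/N.
DENSITY_C = 36.12


@dataclass
class AdmMap:
    sequence: str
    plotted: np.ndarray          # (N, N) bool, strictly upper triangle used
    cutoffs: dict[int, float] = field(default_factory=dict)
    D: float | None = None

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def density(self) -> float:
        n = self.n
        iu = np.triu_indices(n, k=1)
        return float(self.plotted[iu].sum()) / len(iu[0])

    def to_edge_tsv(self, path) -> None:
        ii, jj = np.nonzero(np.triu(self.plotted, k=1))
        with open(path, "w") as fh:
            fh.write("i\tj\n")
            for a, b in zip(ii + 1, jj + 1):
                fh.write(f"{a}\t{b}\n")


@dataclass
class ScanProfiles:
    delta_rho_v: np.ndarray      # Δρ_i^v, index 0 = residue 1
    delta_rho_h: np.ndarray


@dataclass
class CompactRegion:
    start: int                   # 1-based inclusive
    end: int
    eta: float

    def as_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "eta": self.eta}


def _mean_matrix(sequence: str, stats: DistanceStatistics) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (mean distance, range) matrices for a sequence; NaN = no entry."""
    n = len(sequence)
    types = np.array([AA_INDEX[AA1_TO_3[c]] for c in sequence])
    mlab = _ranges_for_length(n, stats.m_max)
    ii, jj = np.triu_indices(n, k=1)
    m = mlab[jj - ii]
    means = np.full((n, n), np.nan)
    means[ii, jj] = stats.mean[types[ii], types[jj], m]
    mm = np.zeros((n, n), dtype=np.int64)
    mm[ii, jj] = m
    return means, mm


def range_cutoffs(stats: DistanceStatistics, D: float) -> dict[int, float]:
    """Cutoff distance per range M from P(M)_c = (D/M)·P(M)_t.

    P(M)_t is the number of statistically significant pair types stored
    for range M; the cutoff is the ⌈P_c⌉-th smallest of their mean
    distances (capped at all of them).  Ranges with no entries get no
    cutoff.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    cutoffs: dict[int, float] = {}
    iu = np.triu_indices(stats.mean.shape[0])
    for m in range(1, stats.m_max + 1):
        means = stats.mean[iu[0], iu[1], m]
        means = np.sort(means[~np.isnan(means)])
        p_t = len(means)
        if p_t == 0:
            warnings.warn(f"range M={m}: no significant entries, no cutoff")
            continue
        p_c = int(np.ceil((D / m) * p_t))
        p_c = min(p_c, p_t)
        if p_c < 1:
            continue
        cutoffs[m] = float(means[p_c - 1])
    return cutoffs


def build_map(sequence: str, stats: DistanceStatistics,
              cutoffs: dict[int, float], D: float | None = None) -> AdmMap:
    """Plot cell (i, j) iff the pair's stored mean distance ≤ cutoff(M)."""
    n = len(sequence)
    if n < 2:
        raise ValueError("sequence too short")
    means, mm = _mean_matrix(sequence, stats)
    cut = np.full(stats.m_max + 1, -np.inf)
    for m, c in cutoffs.items():
        cut[m] = c
    plotted = np.zeros((n, n), dtype=bool)
    ii, jj = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore"):
        plotted[ii, jj] = means[ii, jj] <= cut[mm[ii, jj]]
    return AdmMap(sequence, plotted, cutoffs=dict(cutoffs), D=D)


def calibrate_density(sequence: str, stats: DistanceStatistics,
                      C: float = DENSITY_C, tol: float = 0.005,
                      max_iter: int = 60) -> tuple[float, AdmMap]:
    """Find D so the map density matches the target ρ_av = C/N (bisection).

    Density is a monotone step function of D, so bisection converges to
    the step nearest the target.  Returns (D, map at D); warns when the
    target is unreachable with the stored pair types.
    """
    n = len(sequence)
    target = C / n
    if target > 1:
        raise ValueError(f"target density C/N = {target:.3f} exceeds 1")

    def density_at(d: float) -> tuple[float, AdmMap]:
        amap = build_map(sequence, stats, range_cutoffs(stats, d), D=d)
        return amap.density, amap

    lo, hi = 1e-6, 1.0
    dens_hi, map_hi = density_at(hi)
    while dens_hi < target and hi < stats.m_max * 4:
        hi *= 2
        dens_hi, map_hi = density_at(hi)
    if dens_hi < target:
        warnings.warn(
            f"calibration target {target:.4f} unreachable "
            f"(max density {dens_hi:.4f}); returning best-effort D")
        return hi, map_hi
    best_d, best_map, best_err = hi, map_hi, abs(dens_hi - target)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        dens, amap = density_at(mid)
        if abs(dens - target) < best_err:
            best_d, best_map, best_err = mid, amap, abs(dens - target)
        if dens < target:
            lo = mid
        else:
            hi = mid
        if best_err <= tol and hi - lo < 1e-4:
            break
    if best_err > tol:
        warnings.warn(f"calibrated density {best_map.density:.4f} misses "
                      f"target {target:.4f} by {best_err:.4f}")
    return best_d, best_map


def scan_profiles(amap: AdmMap) -> ScanProfiles:
    """Density differences Δρ_i between the two parts of the map cut at i.

    Convention (cells are pairs (a, b), a < b, 1-based):
      Δρ_i^v = ρ({a < b ≤ i}) − ρ({a ≤ i < b})   (vertical line at i)
      Δρ_i^h = ρ({i ≤ a < b}) − ρ({a < i ≤ b})   (horizontal line at i)
    A line at the map edge does not divide the map: Δρ_i = 0 when either
    part has zero area.
    """
    n = amap.n
    if n < 3:
        raise ValueError("need at least 3 residues")
    P = np.triu(amap.plotted, k=1).astype(np.int64)
    # cum[i, j] = number of plotted cells (a, b) with a <= i and b <= j (0-based)
    cum = P.cumsum(axis=0).cumsum(axis=1)
    total = cum[-1, -1]
    dv = np.zeros(n)
    dh = np.zeros(n)
    for i1 in range(1, n + 1):          # 1-based residue index
        i = i1 - 1
        # vertical: triangle {a<b<=i1}: count = cum[i, i]
        tri_cnt = cum[i, i]
        tri_area = i1 * (i1 - 1) // 2
        trap_cnt = cum[i, -1] - cum[i, i]      # a <= i1 < b
        trap_area = i1 * (n - i1)
        if tri_area and trap_area:
            dv[i] = tri_cnt / tri_area - trap_cnt / trap_area
        # horizontal: triangle {i1<=a<b}: cells with a >= i1
        tri2_cnt = _upper_count(cum, i1, n)
        m = n - i1 + 1
        tri2_area = m * (m - 1) // 2
        trap2_cnt = total - tri2_cnt - (cum[i - 1, i - 1] if i >= 1 else 0)
        trap2_area = (i1 - 1) * (n - i1 + 1)
        if tri2_area and trap2_area:
            dh[i] = tri2_cnt / tri2_area - trap2_cnt / trap2_area
    return ScanProfiles(delta_rho_v=dv, delta_rho_h=dh)


def _upper_count(cum: np.ndarray, i1: int, n: int) -> int:
    """Plotted cells (a, b), a < b, with a >= i1 (1-based)."""
    if i1 <= 1:
        return int(cum[-1, -1])
    # total - cells with a <= i1-1  (0-based rows 0..i1-2)
    return int(cum[-1, -1] - cum[i1 - 2, -1])


def predict_regions(profiles: ScanProfiles, amap: AdmMap,
                    min_length: int = 10, smooth: int = 3,
                    prominence_sd: float = 0.5,
                    eta_tie: float = 0.003) -> list[CompactRegion]:
    """Pair Δρ^h peaks (region starts) with Δρ^v peaks (ends), score by η.

    Candidate boundaries are local maxima of the 3-point-smoothed
    profiles, validated by a one-sided prominence: a start peak by how
    far Δρ^h falls over the following ``min_length`` residues (entering
    the region the lower triangle loses density), an end peak by how far
    Δρ^v rose over the preceding ``min_length`` residues.  The one-sided
    rule matters for terminal regions, whose outer boundary peak is
    flattened by the shrinking map edge.  The validation threshold is
    ``prominence_sd`` standard deviations of the profile.  Each start is
    paired with the nearest subsequent end at least ``min_length``
    residues away; overlapping candidates are resolved in favour of the
    higher η, keeping near-ties (within ``eta_tie``).  Regions return
    sorted by η descending.
    """
    dh, dv = profiles.delta_rho_h, profiles.delta_rho_v
    n = len(dh)

    def peak_idx(x: np.ndarray, side: str) -> np.ndarray:
        # candidates located on the smoothed profile, validated on the raw
        # one (smoothing near the map edges flattens genuine boundary peaks)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            xs = np.convolve(x, kernel, mode="same")
        else:
            xs = x
        sd = x.std()
        if sd == 0:
            return np.array([], dtype=int)
        idx, _ = find_peaks(xs)
        keep = []
        for p in idx:
            base = max(p - 1, 0)
            p = base + int(np.argmax(x[base:p + 2]))     # snap to the raw maximum
            if side == "after":
                lo, hi = p + 1, min(n, p + 1 + min_length)
            else:
                lo, hi = max(0, p - min_length), p
            if hi <= lo:
                continue
            if x[p] - x[lo:hi].min() >= prominence_sd * sd and p not in keep:
                keep.append(p)
        return np.asarray(keep, dtype=int)

    starts = peak_idx(dh, "after")
    ends = peak_idx(dv, "before")
    candidates: list[CompactRegion] = []
    for s in starts:
        later = ends[ends >= s + min_length - 1]
        if len(later) == 0:
            continue
        e = int(later[0])
        eta = float(dh[s] + dv[e])
        candidates.append(CompactRegion(start=int(s) + 1, end=e + 1, eta=eta))
    candidates.sort(key=lambda r: r.eta, reverse=True)
    kept: list[CompactRegion] = []
    for cand in candidates:
        clash = [k for k in kept
                 if not (cand.end < k.start or cand.start > k.end)]
        if any(k.eta - cand.eta > eta_tie for k in clash):
            continue
        kept.append(cand)
    kept.sort(key=lambda r: r.eta, reverse=True)
    return kept


def analyze_sequence(sequence: str, stats: DistanceStatistics,
                     D: float | None = None, C: float = DENSITY_C,
                     **region_kw):
    """Full ADM pass: calibrate (or use D), build, scan, predict regions."""
    if D is None:
        D, amap = calibrate_density(sequence, stats, C=C)
    else:
        amap = build_map(sequence, stats, range_cutoffs(stats, D), D=D)
    profiles = scan_profiles(amap)
    regions = predict_regions(profiles, amap, **region_kw)
    return amap, profiles, regions
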