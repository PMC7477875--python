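"""Inter-residue average-distance statistics.

For every pair of amino-acid types (A, B) and every sequence-separation
"range" M, the mean and standard deviation of the Cα–Cα distance is
collected over a corpus of folded structures.  These tables are the
empirical basis of the average-distance-map (ADM) prediction and of the
harmonic statistical potential used for contact-frequency (F-value)
sampling.

Ranges stratify the sequence separation k = |i−j|:
M = 1 for 1 ≤ k ≤ 8, M = 2 for 9 ≤ k ≤ 20, M = 3 for 21 ≤ k ≤ 30, and
decade-wide bins thereafter.  Separations beyond ``m_max`` pool into the
last bin so long chains do not create starved bins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import AA_INDEX, STANDARD_AA, CaStructure

log = logging.getLogger(__name__)

N_AA = len(STANDARD_AA)

#: Largest range label kept by default; k ≤ 200 maps below it, k > 200 pools in.
DEFAULT_M_MAX = 20


def assign_range(k: int, m_max: int = DEFAULT_M_MAX) -> int:
    """Map a sequence separation k = |i−j| ≥ 1 to its range label M."""
    if k < 1:
        raise ValueError(f"sequence separation must be >= 1, got {k}")
    if k <= 8:
        m = 1
    elif k <= 20:
        m = 2
    else:
        # decade bins: 21–30 -> 3, 31–40 -> 4, ...
        m = 3 + (k - 21) // 10
    return min(m, m_max)


def _ranges_for_length(n: int, m_max: int) -> np.ndarray:
    """Range label for every separation 0..n-1 (index 0 unused)."""
    out = np.zeros(n, dtype=np.int64)
    for k in range(1, n):
        out[k] = assign_range(k, m_max)
    return out


@dataclass
class DistanceStatistics:
    """Mean/σ/count of Cα–Cα distance per (type A, type B, range M).

    Stored as dense (20, 20, m_max+1) arrays symmetric in the first two
    axes; entries with zero count are absent.  σ is the population
    standard deviation.
    """

    mean: np.ndarray          # (20, 20, m_max+1), NaN where absent
    sd: np.ndarray
    count: np.ndarray         # int, 0 where absent
    m_max: int = DEFAULT_M_MAX
    corpus_id: str = ""
    min_count: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.mean.shape == (N_AA, N_AA, self.m_max + 1)

    # -- queries ---------------------------------------------------------
    def get(self, a: str, b: str, m: int):
        """(mean, sd, count) for types a, b (3-letter) in range m, or None."""
        ia, ib = AA_INDEX[a], AA_INDEX[b]
        if m > self.m_max or self.count[ia, ib, m] == 0:
            return None
        return (float(self.mean[ia, ib, m]), float(self.sd[ia, ib, m]),
                int(self.count[ia, ib, m]))

    def n_entries(self) -> int:
        iu = np.triu_indices(N_AA)
        return int((self.count[iu[0], iu[1], :] > 0).sum())

    # -- persistence -----------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = []
        for ia in range(N_AA):
            for ib in range(ia, N_AA):
                for m in range(1, self.m_max + 1):
                    c = self.count[ia, ib, m]
                    if c > 0:
                        rows.append((STANDARD_AA[ia], STANDARD_AA[ib], m,
                                     self.mean[ia, ib, m], self.sd[ia, ib, m],
                                     int(c)))
        df = pd.DataFrame(rows, columns=["A", "B", "M", "mean", "sd", "count"])
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, m_max: int | None = None) -> "DistanceStatistics":
        df = pd.read_csv(path, sep="\t")
        mm = int(m_max if m_max is not None else df["M"].max())
        mean = np.full((N_AA, N_AA, mm + 1), np.nan)
        sd = np.zeros((N_AA, N_AA, mm + 1))
        count = np.zeros((N_AA, N_AA, mm + 1), dtype=np.int64)
        for row in df.itertuples(index=False):
            ia, ib = AA_INDEX[row.A], AA_INDEX[row.B]
            m = int(row.M)
            for x, y in ((ia, ib), (ib, ia)):
                mean[x, y, m] = row.mean
                sd[x, y, m] = row.sd
                count[x, y, m] = row.count
        return cls(mean, sd, count, m_max=mm, corpus_id=str(path))


def collect_statistics(corpus: list[CaStructure], min_count: int = 10,
                       m_max: int = DEFAULT_M_MAX,
                       corpus_id: str = "") -> DistanceStatistics:
    """Pool Cα–Cα distances over all residue pairs of all corpus structures.

    Entries observed fewer than ``min_count`` times are dropped — these
    are the "statistically significant" pair types the downstream analyses
    use.  Unknown residue names were already filtered at read time.
    """
    if not corpus:
        raise ValueError("empty structure corpus")
    s1 = np.zeros((N_AA, N_AA, m_max + 1))
    s2 = np.zeros((N_AA, N_AA, m_max + 1))
    cnt = np.zeros((N_AA, N_AA, m_max + 1), dtype=np.int64)
    for st in corpus:
        coords = st.ca_coords
        n = len(st)
        types = np.array([AA_INDEX[r] for r in st.resnames])
        mlab = _ranges_for_length(n, m_max)
        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        m = mlab[jj - ii]
        ta, tb = types[ii], types[jj]
        np.add.at(s1, (ta, tb, m), d)
        np.add.at(s2, (ta, tb, m), d * d)
        np.add.at(cnt, (ta, tb, m), 1)
    # symmetrize (A,B) with (B,A)
    s1 = s1 + np.swapaxes(s1, 0, 1) * (1 - np.eye(N_AA))[:, :, None]
    s2 = s2 + np.swapaxes(s2, 0, 1) * (1 - np.eye(N_AA))[:, :, None]
    cnt = cnt + np.swapaxes(cnt, 0, 1) * (1 - np.eye(N_AA, dtype=np.int64))[:, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean**2
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    drop = cnt < min_count
    mean[drop] = np.nan
    sd[drop] = 0.0
    cnt = np.where(drop, 0, cnt)
    return DistanceStatistics(mean, sd, cnt, m_max=m_max,
                              corpus_id=corpus_id, min_count=min_count)


def merge_statistics(a: DistanceStatistics, b: DistanceStatistics,
                     min_count: int | None = None) -> DistanceStatistics:
    """Count-weighted merge of two tables (pooled means and second moments)."""
    if a.m_max != b.m_max:
        raise ValueError("tables have different m_max")
    ca, cb = a.count.astype(float), b.count.astype(float)
    ma = np.nan_to_num(a.mean)
    mb = np.nan_to_num(b.mean)
    s1 = ca * ma + cb * mb
    s2 = ca * (a.sd**2 + ma**2) + cb * (b.sd**2 + mb**2)
    cnt = a.count + b.count
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.clip(s2 / cnt - mean**2, 0.0, None)
    sd = np.sqrt(var)
    mc = min_count if min_count is not None else min(a.min_count, b.min_count)
    drop = cnt < mc
    mean[drop] = np.nan
    sd[drop] = 0.0
    cnt = np.where(drop, 0, cnt)
    return DistanceStatistics(mean, sd, cnt, m_max=a.m_max,
                              corpus_id=f"{a.corpus_id}+{b.corpus_id}",
                              min_count=mc)
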