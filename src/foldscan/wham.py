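"""Weighted histogram analysis (WHAM) over multi-temperature (E, Q) samples.

The self-consistent WHAM equations on a 2-D (energy, order-parameter)
histogram estimate the density of states

    Ω(E, Q) = Σ_k H_k(E, Q) / Σ_k N_k exp(f_k − β_k E),
    exp(−f_k) = Σ_{E,Q} Ω(E, Q) exp(−β_k E),

from which free-energy profiles F(Q; T) = −k_BT ln Σ_E Ω e^{−E/k_BT},
the heat capacity C_v(T) = (⟨E²⟩ − ⟨E⟩²)/T², and the folding transition
temperature T_f (the C_v peak) follow.  k_B = 1 throughout; temperatures
are kT/ε like the simulation ladder.  All sums run in log space.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

_NEG_INF = -np.inf


@dataclass
class WhamResult:
    q_centers: np.ndarray
    free_energy: dict                 # temperature -> F(Q) array, in ε, min 0
    t_grid: np.ndarray
    c_v: np.ndarray
    t_f: float
    log_dos: np.ndarray = None        # (nE, nQ), up to a constant
    e_centers: np.ndarray = None
    f_k: np.ndarray = None
    n_iter: int = 0

    def free_energy_tsv(self, path) -> None:
        temps = sorted(self.free_energy)
        with open(path, "w") as fh:
            fh.write("Q\t" + "\t".join(f"F_T{t:.4f}" for t in temps) + "\n")
            for qi, q in enumerate(self.q_centers):
                row = "\t".join(f"{self.free_energy[t][qi]:.6f}" for t in temps)
                fh.write(f"{q:.4f}\t{row}\n")

    def heat_capacity_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("T\tC_v\n")
            for t, c in zip(self.t_grid, self.c_v):
                fh.write(f"{t:.6f}\t{c:.6f}\n")


def wham_analysis(temperatures, energies, q_values,
                  query_temps=None, n_e_bins: int = 50, n_q_bins: int = 40,
                  tol: float = 1e-7, max_iter: int = 10000,
                  t_grid=None) -> WhamResult:
    """Self-consistent WHAM over per-temperature (E, Q) sample series.

    ``temperatures``: K ladder values; ``energies``/``q_values``: (K, n)
    arrays (or lists of 1-D arrays).  With a single temperature WHAM
    reduces exactly to the direct histogram.  Raises when the energy
    histograms of neighbouring temperatures do not overlap (no
    information can flow between windows).
    """
    temps = np.asarray(temperatures, dtype=float)
    k = len(temps)
    e_list = [np.asarray(e, dtype=float) for e in energies]
    q_list = [np.asarray(q, dtype=float) for q in q_values]
    betas = 1.0 / temps
    e_all = np.concatenate(e_list)
    q_all = np.concatenate(q_list)
    e_edges = np.linspace(e_all.min(), e_all.max() + 1e-9, n_e_bins + 1)
    q_edges = np.linspace(min(q_all.min(), 0.0), max(q_all.max(), 1.0) + 1e-9,
                          n_q_bins + 1)
    e_centers = 0.5 * (e_edges[:-1] + e_edges[1:])
    q_centers = 0.5 * (q_edges[:-1] + q_edges[1:])
    hist = np.stack([np.histogram2d(e_list[i], q_list[i],
                                    bins=(e_edges, q_edges))[0]
                     for i in range(k)])                      # (K, nE, nQ)
    n_k = hist.sum(axis=(1, 2))

    if k > 1:
        # overlap diagnostic: successive windows must share energy bins
        e_occ = hist.sum(axis=2) > 0
        for a in range(k - 1):
            if not (e_occ[a] & e_occ[a + 1]).any():
                raise RuntimeError(
                    f"energy histograms of temperatures {temps[a]:.4f} and "
                    f"{temps[a + 1]:.4f} do not overlap; WHAM cannot converge")

    h_tot = hist.sum(axis=0)                                  # (nE, nQ)
    log_h = np.where(h_tot > 0, np.log(np.maximum(h_tot, 1)), _NEG_INF)
    log_nk = np.log(n_k)
    f_k = np.zeros(k)
    # -beta_k * E_e, (K, nE)
    be = -np.outer(betas, e_centers)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # log denominator per E bin: logsum_k [log N_k + f_k - beta_k E]
        log_den = logsumexp(log_nk[:, None] + f_k[:, None] + be, axis=0)  # (nE,)
        log_dos = log_h - log_den[:, None]
        # new f_k = -log sum_{E,Q} dos * exp(-beta_k E)
        mask = h_tot > 0
        contrib = log_dos[None, :, :] + be[:, :, None]
        contrib = np.where(mask[None, :, :], contrib, _NEG_INF)
        f_new = -logsumexp(contrib.reshape(k, -1), axis=1)
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f_k))
        f_k = f_new
        if delta < tol:
            break
    log_den = logsumexp(log_nk[:, None] + f_k[:, None] + be, axis=0)
    log_dos = np.where(h_tot > 0, log_h - log_den[:, None], _NEG_INF)

    if query_temps is None:
        query_temps = [float(temps[0]), float(temps[-1])]
    free_energy = {}
    for t in query_temps:
        b = 1.0 / t
        lw = log_dos - b * e_centers[:, None]                 # (nE, nQ)
        log_pq = logsumexp(lw, axis=0)
        f_q = -t * log_pq
        finite = np.isfinite(f_q)
        if finite.any():
            f_q = f_q - f_q[finite].min()
        free_energy[float(t)] = f_q

    if t_grid is None:
        t_grid = np.linspace(temps.min() * 0.95, temps.max() * 1.05, 400)
    t_grid = np.asarray(t_grid, dtype=float)
    c_v = np.empty_like(t_grid)
    ld_flat = log_dos[np.isfinite(log_dos)]
    e_flat = np.broadcast_to(e_centers[:, None], log_dos.shape)[np.isfinite(log_dos)]
    for i, t in enumerate(t_grid):
        lw = ld_flat - e_flat / t
        lz = logsumexp(lw)
        w = np.exp(lw - lz)
        e_mean = float(np.sum(w * e_flat))
        e2_mean = float(np.sum(w * e_flat**2))
        c_v[i] = (e2_mean - e_mean**2) / t**2
    t_f = float(t_grid[int(np.argmax(c_v))])
    return WhamResult(q_centers, free_energy, t_grid, c_v, t_f,
                      log_dos=log_dos, e_centers=e_centers, f_k=f_k,
                      n_iter=n_iter)


def direct_free_energy(q_values, temperature: float, q_edges) -> np.ndarray:
    """−kT·log histogram(Q) from a single-temperature trajectory (the
    one-window limit WHAM must reproduce)."""
    hist, _ = np.histogram(np.asarray(q_values), bins=q_edges)
    with np.errstate(divide="ignore"):
        f = -temperature * np.log(hist.astype(float))
    finite = np.isfinite(f)
    return f - f[finite].min()
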