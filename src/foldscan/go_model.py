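"""Orientation-dependent coarse-grained Gō model with replica-exchange MC.

The chain is a Cα bead model whose energy rewards only interactions
present in the native structure:

    E = Σ K_θ (θ_i − θ_i0)²
      + Σ { K_φ¹ [1 − cos(φ_i − φ_i0)] + K_φ³ [1 − cos 3(φ_i − φ_i0)] }
      + Σ_NC ε C_ij [ 5 (r_ij0/r_ij)¹² − B_ij · 6 (r_ij0/r_ij)¹⁰ ]
      + Σ_NNC (4 Å / r_ij)¹²

with K_θ = 20ε, K_φ¹ = ε, K_φ³ = 0.5ε.  A native contact exists when at
least one heavy-atom pair of two residues (|i−j| ≥ 4) sits within the
sum of their van der Waals radii + 1.4 Å; C_ij is the heavy-atom contact
count normalized to mean 1.  The orientation factor
B_ij = 1 − (Θ_ij − Θ_ij0)²/a_Θ² (0 beyond |ΔΘ| = a_Θ = 0.6π) compares
the angle Θ_ij between the side-chain-mimicking bisector vectors
h_i = r_{i,i−1} + r_{i,i+1} with its native value; terminal residues,
where h is undefined, get B = 1.  The constant offsets in the dihedral
wells make the native conformation the zero of the local terms, so the
native-state energy is exactly −Σ ε C_ij; offsets cancel in every ΔE.

Sampling: one MC step = N pivot moves then N crankshaft moves (segment
≤ N/2), each Metropolis-judged; replicas at a temperature ladder attempt
alternating even/odd neighbour swaps every ``exchange_interval`` steps
with acceptance min(1, exp[(β_a − β_b)(E_a − E_b)]).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .structure import DEFAULT_VDW, VDW_RADII, CaStructure

log = logging.getLogger(__name__)


@dataclass
class GoParameters:
    """Energy-function constants, in units of ε (and Å for lengths)."""

    k_theta: float = 20.0
    k_phi1: float = 1.0
    k_phi3: float = 0.5
    a_theta: float = 0.6 * np.pi
    sigma_nnc: float = 4.0          # excluded-volume diameter, Å
    epsilon: float = 1.0
    formed_factor: float = 1.2      # contact counts as formed below 1.2·r0

    def __post_init__(self) -> None:
        for name in ("k_theta", "k_phi1", "k_phi3", "a_theta",
                     "sigma_nnc", "epsilon", "formed_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GoTopology:
    """Native geometry: reference angles plus the native contact set."""

    coords0: np.ndarray            # (N, 3) native Cα coordinates
    theta0: np.ndarray             # (N-2,) native bond angles
    phi0: np.ndarray               # (N-3,) native dihedrals
    nc_i: np.ndarray               # contact partners (0-based)
    nc_j: np.ndarray
    nc_r0: np.ndarray              # native Cα–Cα distance per contact
    nc_c: np.ndarray               # C_ij, normalized to mean 1
    nc_theta0: np.ndarray          # native orientation angle Θ_ij0
    nc_term: np.ndarray            # bool: contact involves a terminus (B=1)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.coords0)

    @property
    def n_contacts(self) -> int:
        return len(self.nc_i)

    @property
    def is_nc(self) -> np.ndarray:
        m = np.zeros((self.n, self.n), dtype=bool)
        m[self.nc_i, self.nc_j] = True
        m[self.nc_j, self.nc_i] = True
        return m

    def contact_separations(self) -> np.ndarray:
        return np.abs(self.nc_j - self.nc_i)

    def to_json(self, path) -> None:
        obj = {
            "n": self.n,
            "coords0": self.coords0.tolist(),
            "theta0": self.theta0.tolist(),
            "phi0": self.phi0.tolist(),
            "contacts": [
                {"i": int(i) + 1, "j": int(j) + 1, "r0": float(r),
                 "C": float(c), "theta0": float(t), "terminal": bool(tm)}
                for i, j, r, c, t, tm in zip(
                    self.nc_i, self.nc_j, self.nc_r0, self.nc_c,
                    self.nc_theta0, self.nc_term)
            ],
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GoTopology":
        with open(path) as fh:
            obj = json.load(fh)
        con = obj["contacts"]
        return cls(
            coords0=np.asarray(obj["coords0"]),
            theta0=np.asarray(obj["theta0"]),
            phi0=np.asarray(obj["phi0"]),
            nc_i=np.asarray([c["i"] - 1 for c in con], dtype=np.int64),
            nc_j=np.asarray([c["j"] - 1 for c in con], dtype=np.int64),
            nc_r0=np.asarray([c["r0"] for c in con]),
            nc_c=np.asarray([c["C"] for c in con]),
            nc_theta0=np.asarray([c["theta0"] for c in con]),
            nc_term=np.asarray([c["terminal"] for c in con], dtype=bool),
            meta=obj.get("meta", {}),
        )


def extract_topology(structure: CaStructure,
                     contact_margin: float = 1.4,
                     min_separation: int = 4,
                     ca_fallback_cutoff: float = 6.5) -> GoTopology:
    """Native topology from an all-atom (or Cα-only synthetic) structure.

    Heavy-atom rule: residues i, j (|i−j| ≥ 4) are a native contact when
    any heavy-atom pair is within vdW_a + vdW_b + 1.4 Å; C_ij is the
    number of such atom pairs divided by its mean over contacts.  When no
    heavy atoms are present (synthetic Cα traces) a fallback applies:
    contact iff Cα distance < 6.5 Å, C_ij ≡ 1, flagged in ``meta``.
    """
    coords = structure.ca_coords
    n = len(structure)
    theta0 = _kernels.bond_angles(coords)
    phi0 = _kernels.dihedral_angles(coords)
    use_heavy = structure.has_heavy_atoms
    pairs: list[tuple[int, int, float]] = []
    if use_heavy:
        atom_xyz = [np.asarray([a[1] for a in r.heavy_atoms]) for r in structure.residues]
        atom_rad = [np.asarray([VDW_RADII.get(a[0], DEFAULT_VDW)
                                for a in r.heavy_atoms]) for r in structure.residues]
        for i in range(n):
            if len(atom_xyz[i]) == 0:
                raise ValueError(f"residue {i + 1} has no heavy atoms")
            for j in range(i + min_separation, n):
                d = np.linalg.norm(atom_xyz[i][:, None, :] - atom_xyz[j][None, :, :],
                                   axis=2)
                thr = atom_rad[i][:, None] + atom_rad[j][None, :] + contact_margin
                cnt = int((d < thr).sum())
                if cnt > 0:
                    pairs.append((i, j, float(cnt)))
    else:
        log.info("no heavy atoms: using Ca-only contact rule (< %.1f A)",
                 ca_fallback_cutoff)
        for i in range(n):
            for j in range(i + min_separation, n):
                if np.linalg.norm(coords[i] - coords[j]) < ca_fallback_cutoff:
                    pairs.append((i, j, 1.0))
    if not pairs:
        raise ValueError("structure has no native contacts")
    nc_i = np.asarray([p[0] for p in pairs], dtype=np.int64)
    nc_j = np.asarray([p[1] for p in pairs], dtype=np.int64)
    raw_c = np.asarray([p[2] for p in pairs])
    nc_c = raw_c / raw_c.mean()
    nc_r0 = np.linalg.norm(coords[nc_i] - coords[nc_j], axis=1)
    h = _kernels._h_vectors(coords)
    nc_term = (nc_i == 0) | (nc_i == n - 1) | (nc_j == 0) | (nc_j == n - 1)
    nc_theta0 = np.asarray([
        0.0 if t else _kernels.orientation_angle(h, int(i), int(j))
        for i, j, t in zip(nc_i, nc_j, nc_term)])
    return GoTopology(coords.copy(), theta0, phi0, nc_i, nc_j, nc_r0,
                      nc_c, nc_theta0, nc_term,
                      meta={"contact_rule": "heavy" if use_heavy else "ca",
                            "name": structure.name})


def orientation_factor(coords: np.ndarray, i: int, j: int,
                       topology: GoTopology,
                       params: GoParameters | None = None) -> float:
    """B_ij ∈ [0, 1] for the current conformation (B = 1 at a terminus)."""
    params = params or GoParameters()
    n = len(coords)
    if i in (0, n - 1) or j in (0, n - 1):
        return 1.0
    h = _kernels._h_vectors(np.ascontiguousarray(coords, dtype=float))
    theta = _kernels.orientation_angle(h, i, j)
    sel = np.nonzero((topology.nc_i == min(i, j)) & (topology.nc_j == max(i, j)))[0]
    if len(sel) == 0:
        raise KeyError(f"({i}, {j}) is not a native contact")
    dth = abs(theta - topology.nc_theta0[sel[0]])
    return float(1.0 - dth**2 / params.a_theta**2) if dth < params.a_theta else 0.0


def go_energy(coords: np.ndarray, topology: GoTopology,
              params: GoParameters | None = None) -> float:
    """Total energy in units of ε; huge for overlapping beads."""
    params = params or GoParameters()
    return float(params.epsilon * _kernels.go_energy(
        np.ascontiguousarray(coords, dtype=float),
        topology.theta0, topology.phi0,
        topology.nc_i, topology.nc_j, topology.nc_r0, topology.nc_c,
        topology.nc_theta0, topology.nc_term, topology.is_nc,
        params.k_theta, params.k_phi1, params.k_phi3,
        params.a_theta, params.sigma_nnc))


def go_energy_terms(coords: np.ndarray, topology: GoTopology,
                    params: GoParameters | None = None) -> dict:
    """The four energy terms separately: bond angle, dihedral, native
    contacts, non-native repulsion (all in units of ε).

    At the native state the angle and dihedral terms vanish and every
    native contact sits at its minimum with B = 1, so the native term is
    exactly −Σ εC_ij; the non-native term is the residual steric
    background.
    """
    params = params or GoParameters()
    x = np.ascontiguousarray(coords, dtype=float)
    th = _kernels.bond_angles(x)
    e_angle = float(params.k_theta * ((th - topology.theta0) ** 2).sum())
    ph = _kernels.dihedral_angles(x)
    d = ph - topology.phi0
    e_dihedral = float((params.k_phi1 * (1 - np.cos(d))
                        + params.k_phi3 * (1 - np.cos(3 * d))).sum())
    h = _kernels._h_vectors(x)
    e_native = 0.0
    for c in range(topology.n_contacts):
        i, j = int(topology.nc_i[c]), int(topology.nc_j[c])
        r = float(np.linalg.norm(x[i] - x[j]))
        if topology.nc_term[c]:
            b = 1.0
        else:
            dth = abs(_kernels.orientation_angle(h, i, j)
                      - topology.nc_theta0[c])
            b = 1 - dth**2 / params.a_theta**2 if dth < params.a_theta else 0.0
        z = topology.nc_r0[c] / r
        e_native += params.epsilon * topology.nc_c[c] * (5 * z**12 - 6 * b * z**10)
    is_nc = topology.is_nc
    n = len(x)
    e_nnc = 0.0
    for i in range(n):
        for j in range(i + 4, n):
            if not is_nc[i, j]:
                e_nnc += (params.sigma_nnc / np.linalg.norm(x[i] - x[j])) ** 12
    return {"angle": e_angle, "dihedral": e_dihedral,
            "native": float(e_native), "non_native": float(e_nnc)}


def q_value(coords: np.ndarray, topology: GoTopology,
            params: GoParameters | None = None) -> float:
    """Fraction of native contacts formed (r < formed_factor · r0)."""
    if topology.n_contacts == 0:
        raise ValueError("topology has no native contacts")
    params = params or GoParameters()
    return float(_kernels.q_value_kernel(
        np.ascontiguousarray(coords, dtype=float),
        topology.nc_i, topology.nc_j, topology.nc_r0, params.formed_factor))


def _seed_for(seed: int, *branch: int) -> int:
    ss = np.random.SeedSequence([seed, *branch])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RemcTrajectory:
    """Per-temperature (E, Q) series plus per-frame native-contact states."""

    ladder: np.ndarray                     # kT/ε, strictly increasing
    energies: np.ndarray                   # (n_temps, n_frames)
    q_values: np.ndarray                   # (n_temps, n_frames)
    contact_states: np.ndarray             # (n_temps, n_frames, n_contacts) uint8
    exchange_attempts: int = 0
    exchange_accepts: int = 0
    exchange_accepts_by_pair: np.ndarray | None = None
    exchange_attempts_by_pair: np.ndarray | None = None
    seed: int = 0
    record_interval: int = 10

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame\ttemp_index\tkT\tE\tQ\n")
            for t in range(len(self.ladder)):
                for fidx in range(self.energies.shape[1]):
                    fh.write(f"{fidx}\t{t}\t{self.ladder[t]:.6f}\t"
                             f"{self.energies[t, fidx]:.6f}\t"
                             f"{self.q_values[t, fidx]:.6f}\n")


def replica_exchange(topology: GoTopology, ladder,
                     equil_steps: int = 100_000, prod_steps: int = 1_000_000,
                     exchange_interval: int = 100, record_interval: int = 10,
                     seed: int = 0, params: GoParameters | None = None,
                     start_coords: np.ndarray | None = None) -> RemcTrajectory:
    """Replica-exchange Metropolis MC over a temperature ladder.

    Replicas start from the native conformation (or ``start_coords``);
    the equilibration phase is discarded.  A single-temperature ladder
    degenerates to plain MC.  Deterministic for a given seed.
    """
    params = params or GoParameters()
    ladder = np.asarray(ladder, dtype=float)
    if len(ladder) > 1 and not (np.diff(ladder) > 0).all():
        raise ValueError("temperature ladder must be strictly increasing")
    k = len(ladder)
    top = topology
    is_nc = top.is_nc
    states = [np.array(start_coords if start_coords is not None
                       else top.coords0, dtype=float) for _ in range(k)]
    start_angles = _kernels.bond_angles(states[0])
    if (start_angles >= np.pi - 1e-9).any():
        raise ValueError("start conformation has a straight (θ = π) bond "
                         "angle; the bisector vectors h are undefined there")
    energies = np.array([go_energy(s, top, params) for s in states])
    if not np.isfinite(energies[0]) or energies[0] >= 1e29:
        raise ValueError("start conformation has overlapping beads")

    def run_block(t_idx: int, n_steps: int, block: int, record: bool):
        e, re_, rq, rcs, na, nt = _kernels.go_mc_block(
            states[t_idx], energies[t_idx], n_steps, ladder[t_idx],
            top.theta0, top.phi0, top.nc_i, top.nc_j, top.nc_r0, top.nc_c,
            top.nc_theta0, top.nc_term, is_nc,
            params.k_theta, params.k_phi1, params.k_phi3, params.a_theta,
            params.sigma_nnc, params.formed_factor,
            record_interval if record else n_steps + 1,
            _seed_for(seed, t_idx, block))
        # guard against float drift of the incremental bookkeeping
        if block % 100 == 99:
            e = go_energy(states[t_idx], top, params)
        energies[t_idx] = e
        return re_, rq, rcs

    n_blocks_eq = max(1, equil_steps // exchange_interval) if equil_steps else 0
    n_blocks = prod_steps // exchange_interval
    rec_per_block = exchange_interval // record_interval
    n_frames = n_blocks * rec_per_block
    rec_e = np.empty((k, n_frames))
    rec_q = np.empty((k, n_frames))
    rec_cs = np.zeros((k, n_frames, top.n_contacts), dtype=np.uint8)
    swap_rng = np.random.default_rng(_seed_for(seed, 999))
    ex_att = ex_acc = 0
    att_pair = np.zeros(max(k - 1, 1), dtype=np.int64)
    acc_pair = np.zeros(max(k - 1, 1), dtype=np.int64)

    def attempt_swaps(block: int) -> None:
        nonlocal ex_att, ex_acc
        start = block % 2
        for a in range(start, k - 1, 2):
            b = a + 1
            ex_att += 1
            att_pair[a] += 1
            d = (1.0 / ladder[a] - 1.0 / ladder[b]) * (energies[a] - energies[b])
            if d >= 0 or swap_rng.random() < np.exp(d):
                states[a], states[b] = states[b], states[a]
                energies[a], energies[b] = energies[b], energies[a]
                ex_acc += 1
                acc_pair[a] += 1

    for block in range(n_blocks_eq):
        for t in range(k):
            run_block(t, exchange_interval, block, record=False)
        attempt_swaps(block)
    for block in range(n_blocks):
        lo = block * rec_per_block
        for t in range(k):
            re_, rq, rcs = run_block(t, exchange_interval,
                                     n_blocks_eq + block, record=True)
            rec_e[t, lo:lo + rec_per_block] = re_
            rec_q[t, lo:lo + rec_per_block] = rq
            rec_cs[t, lo:lo + rec_per_block] = rcs
        attempt_swaps(n_blocks_eq + block)
    return RemcTrajectory(ladder, rec_e, rec_q, rec_cs,
                          exchange_attempts=ex_att, exchange_accepts=ex_acc,
                          exchange_accepts_by_pair=acc_pair,
                          exchange_attempts_by_pair=att_pair,
                          seed=seed, record_interval=record_interval)


def contact_map_at_q(traj: RemcTrajectory, topology: GoTopology,
                     q_center: float, half_width: float = 0.05,
                     long_range_min: int = 16):
    """Native-contact formation frequencies over frames with |Q − Q₀| ≤ w.

    Returns (frequency per native contact, mask of long-range contacts
    with k = |i−j| ≥ ``long_range_min``, number of frames used).
    """
    sel = np.abs(traj.q_values - q_center) <= half_width
    n_frames = int(sel.sum())
    if n_frames == 0:
        raise ValueError(f"no frames with |Q - {q_center}| <= {half_width}")
    freq = traj.contact_states[sel].mean(axis=0)
    long_range = topology.contact_separations() >= long_range_min
    return freq, long_range, n_frames


def temperature_ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Geometric ladder of n temperatures in [t_min, t_max]."""
    return np.geomspace(t_min, t_max, n)
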