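"""Gō model: topology rules, energy oracle, sampler and order parameter."""
import numpy as np
import pytest

from foldscan import _kernels, go_model, synthetic
from foldscan.go_model import GoParameters, GoTopology
from foldscan.structure import CaStructure, Residue


# ---------------------------------------------------------------------------
# topology extraction
# ---------------------------------------------------------------------------

def _chain_with_probe_atoms(gap):
    """Straight 8-mer with one extra atom on residues 1 and 6 whose
    carbon-carbon gap is vdW sum (3.4 Å) + ``gap``."""
    coords = np.array([[i * 3.8, 0.0, 0.0] for i in range(8)])
    residues = []
    for i, c in enumerate(coords):
        atoms = [("C", c)]
        if i == 0:
            atoms.append(("C", c + np.array([0.0, 5.0, 0.0])))
        if i == 5:
            probe = coords[0] + np.array([0.0, 5.0 + 3.4 + gap, 0.0])
            atoms.append(("C", probe))
        residues.append(Residue("ALA", c, heavy_atoms=atoms))
    return CaStructure(residues, synthetic=True)


def test_contact_rule_boundary():
    # closest heavy atoms at vdW sum + 1.5 A: NOT a native contact
    st = _chain_with_probe_atoms(1.5)
    with pytest.raises(ValueError):      # no contacts at all in this chain
        go_model.extract_topology(st)
    # at vdW sum + 1.3 A: a contact
    st = _chain_with_probe_atoms(1.3)
    top = go_model.extract_topology(st)
    assert top.n_contacts == 1
    assert (int(top.nc_i[0]), int(top.nc_j[0])) == (0, 5)


def test_local_contacts_excluded():
    # overlapping atoms at |i-j| = 3 must be ignored
    coords = np.array([[i * 3.8, 0.0, 0.0] for i in range(8)])
    residues = []
    for i, c in enumerate(coords):
        atoms = [("C", c)]
        if i in (1, 4):                  # separation 3, overlapping probes
            atoms.append(("C", np.array([7.0, 5.0, 0.0])))
        residues.append(Residue("ALA", c, heavy_atoms=atoms))
    with pytest.raises(ValueError):
        go_model.extract_topology(CaStructure(residues, synthetic=True))


def test_contact_strengths_normalized(hairpin_top):
    assert hairpin_top.nc_c.mean() == pytest.approx(1.0, abs=1e-9)
    assert (hairpin_top.contact_separations() >= 4).all()
    assert (hairpin_top.nc_r0 > 0).all()


def test_topology_json_roundtrip(hairpin_top, tmp_path):
    p = tmp_path / "top.json"
    hairpin_top.to_json(p)
    back = GoTopology.from_json(p)
    assert np.allclose(back.coords0, hairpin_top.coords0)
    assert (back.nc_i == hairpin_top.nc_i).all()
    assert np.allclose(back.nc_theta0, hairpin_top.nc_theta0)


# ---------------------------------------------------------------------------
# orientation factor and energy
# ---------------------------------------------------------------------------

def test_orientation_factor_limits(hairpin_top):
    params = GoParameters()
    interior = [(int(i), int(j)) for i, j, t in
                zip(hairpin_top.nc_i, hairpin_top.nc_j, hairpin_top.nc_term)
                if not t]
    i, j = interior[0]
    # native orientation -> B = 1
    assert go_model.orientation_factor(hairpin_top.coords0, i, j,
                                       hairpin_top) == pytest.approx(1.0)
    # quadratic falloff: ΔΘ = a/2 -> 0.75; ΔΘ = a -> 0  (direct formula)
    a = params.a_theta
    for dth, expect in [(a / 2, 0.75), (a, 0.0), (1.5 * a, 0.0)]:
        b = 1.0 - dth**2 / a**2 if dth < a else 0.0
        assert b == pytest.approx(expect)


def test_terminal_residue_orientation_is_one(hairpin_top):
    term = [(int(i), int(j)) for i, j, t in
            zip(hairpin_top.nc_i, hairpin_top.nc_j, hairpin_top.nc_term) if t]
    for i, j in term:
        assert go_model.orientation_factor(hairpin_top.coords0, i, j,
                                           hairpin_top) == 1.0


def _oracle_energy(x, top, p):
    """Independent term-by-term energy implementation (pure numpy)."""
    n = len(x)
    e = 0.0
    for r in range(1, n - 1):
        u = x[r - 1] - x[r]
        v = x[r + 1] - x[r]
        th = np.arccos(np.clip(np.dot(u, v) / np.linalg.norm(u)
                               / np.linalg.norm(v), -1, 1))
        e += p.k_theta * (th - top.theta0[r - 1]) ** 2
    for d in range(n - 3):
        b1, b2, b3 = x[d + 1] - x[d], x[d + 2] - x[d + 1], x[d + 3] - x[d + 2]
        c1, c2 = np.cross(b1, b2), np.cross(b2, b3)
        ph = np.arctan2(np.dot(b1, c2) * np.linalg.norm(b2), np.dot(c1, c2))
        dd = ph - top.phi0[d]
        e += p.k_phi1 * (1 - np.cos(dd)) + p.k_phi3 * (1 - np.cos(3 * dd))
    h = np.zeros((n, 3))
    for i in range(1, n - 1):
        h[i] = (x[i - 1] - x[i]) + (x[i + 1] - x[i])
    nc = set()
    for c in range(top.n_contacts):
        i, j = int(top.nc_i[c]), int(top.nc_j[c])
        nc.add((i, j))
        r = np.linalg.norm(x[i] - x[j])
        if top.nc_term[c]:
            b = 1.0
        else:
            cth = np.clip(np.dot(h[i], h[j]) / np.linalg.norm(h[i])
                          / np.linalg.norm(h[j]), -1, 1)
            dth = abs(np.arccos(cth) - top.nc_theta0[c])
            b = 1 - dth**2 / p.a_theta**2 if dth < p.a_theta else 0.0
        z = top.nc_r0[c] / r
        e += p.epsilon * top.nc_c[c] * (5 * z**12 - 6 * b * z**10)
    for i in range(n):
        for j in range(i + 4, n):
            if (i, j) not in nc:
                e += (p.sigma_nnc / np.linalg.norm(x[i] - x[j])) ** 12
    return e


def test_energy_matches_independent_oracle(hairpin_top):
    p = GoParameters()
    rng = np.random.default_rng(6)
    x = hairpin_top.coords0 + rng.normal(0, 0.7, size=hairpin_top.coords0.shape)
    assert go_model.go_energy(x, hairpin_top, p) == pytest.approx(
        _oracle_energy(x, hairpin_top, p), abs=1e-9)
    # and at the native state itself
    assert go_model.go_energy(hairpin_top.coords0, hairpin_top, p) == \
        pytest.approx(_oracle_energy(hairpin_top.coords0, hairpin_top, p),
                      abs=1e-9)


def test_native_state_energy_terms(hairpin_top):
    """At the native state the local terms vanish and every native contact
    sits at its minimum, contributing exactly −εC_ij; only the small
    non-native repulsion remains on top of −Σ εC_ij."""
    p = GoParameters()
    e = go_model.go_energy(hairpin_top.coords0, hairpin_top, p)
    contact_sum = -hairpin_top.nc_c.sum() * p.epsilon
    nnc = 0.0
    nc = {(int(i), int(j)) for i, j in zip(hairpin_top.nc_i, hairpin_top.nc_j)}
    x = hairpin_top.coords0
    for i in range(len(x)):
        for j in range(i + 4, len(x)):
            if (i, j) not in nc:
                nnc += (p.sigma_nnc / np.linalg.norm(x[i] - x[j])) ** 12
    assert e - nnc == pytest.approx(contact_sum, abs=1e-9)


def test_distant_contact_contributes_nothing(hairpin_top):
    x = hairpin_top.coords0.copy()
    p = GoParameters()
    c = 0
    i, j = int(hairpin_top.nc_i[c]), int(hairpin_top.nc_j[c])
    z = hairpin_top.nc_r0[c] / 1e6
    assert hairpin_top.nc_c[c] * (5 * z**12 - 6 * z**10) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------

def test_q_value_native_extended_and_half(hairpin_top):
    assert go_model.q_value(hairpin_top.coords0, hairpin_top) == 1.0
    n = hairpin_top.n
    ext = np.zeros((n, 3))
    ext[:, 0] = np.arange(n) * 3.8
    assert go_model.q_value(ext, hairpin_top) == 0.0
    # exactly half the contacts formed
    nc = hairpin_top.n_contacts
    half = GoTopology(
        coords0=hairpin_top.coords0, theta0=hairpin_top.theta0,
        phi0=hairpin_top.phi0,
        nc_i=np.concatenate([hairpin_top.nc_i[:2], np.array([0, 1])]),
        nc_j=np.concatenate([hairpin_top.nc_j[:2], np.array([10, 11])]),
        nc_r0=np.array([*hairpin_top.nc_r0[:2], 1.0, 1.0]),
        nc_c=np.ones(4), nc_theta0=np.zeros(4),
        nc_term=np.array([True] * 4))
    assert go_model.q_value(hairpin_top.coords0, half) == pytest.approx(0.5)


def test_q_requires_contacts(hairpin_top):
    empty = GoTopology(hairpin_top.coords0, hairpin_top.theta0,
                       hairpin_top.phi0, np.empty(0, np.int64),
                       np.empty(0, np.int64), np.empty(0), np.empty(0),
                       np.empty(0), np.empty(0, bool))
    with pytest.raises(ValueError):
        go_model.q_value(hairpin_top.coords0, empty)


# ---------------------------------------------------------------------------
# Monte Carlo sampler
# ---------------------------------------------------------------------------

def _run_block(top, x, e, n_steps, kT, seed, record=100000, p=None):
    p = p or GoParameters()
    return _kernels.go_mc_block(
        x, e, n_steps, kT, top.theta0, top.phi0, top.nc_i, top.nc_j,
        top.nc_r0, top.nc_c, top.nc_theta0, top.nc_term, top.is_nc,
        p.k_theta, p.k_phi1, p.k_phi3, p.a_theta, p.sigma_nnc,
        p.formed_factor, record, seed, 0)


def test_incremental_energy_equals_full_recomputation(hairpin_top):
    p = GoParameters()
    for kT in (0.5, 1.0):
        x = hairpin_top.coords0.copy()
        e0 = go_model.go_energy(x, hairpin_top, p)
        e, *_ = _run_block(hairpin_top, x, e0, 1500, kT, seed=77)
        assert e == pytest.approx(go_model.go_energy(x, hairpin_top, p),
                                  abs=1e-6)


def test_infinite_temperature_accepts_everything(hairpin_top):
    x = hairpin_top.coords0.copy()
    e0 = go_model.go_energy(x, hairpin_top)
    _, _, _, _, n_acc, n_try = _run_block(hairpin_top, x, e0, 200, 1e12,
                                          seed=5)
    assert n_acc / n_try > 0.99          # only θ ≥ π rejections remain


def test_move_set_samples_boltzmann_bond_angle():
    """Detailed balance + ergodicity of pivot/crankshaft moves: on a
    5-mer with only angle terms, the marginal of a bond angle must match
    p(θ) ∝ sin θ · exp(−K_θ(θ−θ0)²/kT) (KS distance < 0.05; samples are
    thinned but still autocorrelated, so a distance bound is the robust
    comparison)."""
    n = 5
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * 3.8
    coords[:, 1] = 0.4 * (np.arange(n) % 2)     # slight zigzag
    theta0 = _kernels.bond_angles(coords)
    phi0 = _kernels.dihedral_angles(coords)
    top = GoTopology(coords, theta0, phi0, np.empty(0, np.int64),
                     np.empty(0, np.int64), np.empty(0), np.empty(0),
                     np.empty(0), np.empty(0, bool))
    p = GoParameters(k_theta=3.0, sigma_nnc=1e-3)   # soft angles, no EV
    kT = 1.0
    x = coords.copy()
    e = go_model.go_energy(x, top, p)
    samples = []
    for block in range(4000):
        e, *_ = _run_block(top, x, e, 2, kT, seed=1000 + block, p=p)
        samples.append(_kernels.bond_angles(x)[1])
    samples = np.asarray(samples[500:])
    grid = np.linspace(1e-3, np.pi - 1e-3, 2000)
    w = np.sin(grid) * np.exp(-p.k_theta * (grid - theta0[1]) ** 2 / kT)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    emp = np.searchsorted(np.sort(samples), grid) / len(samples)
    assert np.max(np.abs(emp - cdf)) < 0.05


def test_trajectory_determinism(hairpin_top):
    ladder = [0.6, 0.9]
    kw = dict(equil_steps=500, prod_steps=1500, exchange_interval=100,
              record_interval=10, seed=21)
    t1 = go_model.replica_exchange(hairpin_top, ladder, **kw)
    t2 = go_model.replica_exchange(hairpin_top, ladder, **kw)
    assert (t1.energies == t2.energies).all()
    assert (t1.q_values == t2.q_values).all()
    assert (t1.contact_states == t2.contact_states).all()


def test_equal_temperature_swaps_always_accepted(hairpin_top):
    traj = go_model.replica_exchange(
        hairpin_top, [0.8, 0.8 + 1e-12], equil_steps=0, prod_steps=1000,
        exchange_interval=100, record_interval=100, seed=3)
    assert traj.exchange_accepts == traj.exchange_attempts > 0


def test_ladder_must_increase(hairpin_top):
    with pytest.raises(ValueError):
        go_model.replica_exchange(hairpin_top, [1.0, 0.9], equil_steps=0,
                                  prod_steps=100)


# ---------------------------------------------------------------------------
# thermodynamics of the desk-scale run (shared session fixture)
# ---------------------------------------------------------------------------

def test_mean_energy_nondecreasing_in_temperature(hairpin_remc):
    means = hairpin_remc.energies.mean(axis=1)
    assert (np.diff(means) > -0.5).all()     # monotone up to sampling noise
    assert means[-1] > means[0] + 5


def test_exchange_acceptance_within_working_band(hairpin_remc):
    acc = (hairpin_remc.exchange_accepts_by_pair
           / np.maximum(hairpin_remc.exchange_attempts_by_pair, 1))
    assert (acc > 0.1).all() and (acc < 0.9).all()


def test_contact_map_at_q_recount_and_native_window(hairpin_top, hairpin_remc):
    freq, long_range, n_frames = go_model.contact_map_at_q(
        hairpin_remc, hairpin_top, q_center=1.0, half_width=0.05)
    assert n_frames > 100
    assert (freq > 0.9).all()                # native window: contacts formed
    assert ((freq >= 0) & (freq <= 1)).all()
    # brute-force recount oracle over the selected frames
    sel = np.abs(hairpin_remc.q_values - 1.0) <= 0.05
    recount = hairpin_remc.contact_states[sel].astype(float).mean(axis=0)
    assert np.allclose(freq, recount)
    assert long_range.sum() == (hairpin_top.contact_separations() >= 16).sum()


def test_contact_map_empty_window_raises(hairpin_top, hairpin_remc):
    with pytest.raises(ValueError):
        go_model.contact_map_at_q(hairpin_remc, hairpin_top,
                                  q_center=-5.0, half_width=0.01)
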