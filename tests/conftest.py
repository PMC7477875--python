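import numpy as np
import pytest

from foldscan import go_model, synthetic


@pytest.fixture(scope="session")
def hairpin():
    return synthetic.make_mini_native("hairpin", 24, seed=0)


@pytest.fixture(scope="session")
def hairpin_top(hairpin):
    return go_model.extract_topology(hairpin)


#: Ladder spanning the 24-mer hairpin's folding transition (T_f ≈ 0.65).
HAIRPIN_LADDER = go_model.temperature_ladder(0.5, 1.1, 8)


@pytest.fixture(scope="session")
def hairpin_remc(hairpin_top):
    """The desk-scale thermodynamics run: 8 temperatures, 2·10⁵ production
    steps after 2·10⁴ equilibration steps, exchanges every 100 steps.
    Shared across tests because it is the expensive fixture."""
    return go_model.replica_exchange(
        hairpin_top, HAIRPIN_LADDER, equil_steps=20_000, prod_steps=200_000,
        exchange_interval=100, record_interval=10, seed=11)


@pytest.fixture(scope="session")
def planted_blocks_case():
    """The two-block compact-region recovery setting shared by the adm
    tests: blocks [5, 25] and [40, 60] in a 70-residue sequence."""
    spec = synthetic.PlantedSpec(length=70, seed=0, blocks=[(5, 25), (40, 60)])
    seq, table = synthetic.make_planted_stats(spec)
    return spec, seq, table


def toy_two_state_dos():
    """Exact two-state density of states: a narrow folded branch around
    E = −30 and an entropy-rich unfolded branch around E = 0."""
    e_f = np.arange(0, 11, dtype=float)
    states_e = np.concatenate([-30 + e_f, -10 + np.arange(0, 21, dtype=float)])
    states_s = np.concatenate([0.6 * e_f, 24 + 0.45 * np.arange(21)])
    states_q = np.concatenate([np.full(11, 0.9), np.full(21, 0.1)])
    return states_e, states_s, states_q
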