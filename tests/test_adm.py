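"""Average distance map: cutoffs, density calibration, region prediction."""
import warnings

import numpy as np
import pytest

from foldscan import adm, synthetic
from foldscan.stats import DEFAULT_M_MAX, N_AA, DistanceStatistics
from foldscan.structure import AA_INDEX


def _table_with_means(per_range_means, sigma=1.0):
    """Statistics table whose range-M significant means are exactly the
    given lists (assigned to arbitrary distinct pair types)."""
    mean = np.full((N_AA, N_AA, DEFAULT_M_MAX + 1), np.nan)
    sd = np.zeros((N_AA, N_AA, DEFAULT_M_MAX + 1))
    count = np.zeros((N_AA, N_AA, DEFAULT_M_MAX + 1), dtype=np.int64)
    iu = np.triu_indices(N_AA)
    for m, means in per_range_means.items():
        for k, mu in enumerate(means):
            a, b = iu[0][k], iu[1][k]
            mean[a, b, m] = mean[b, a, m] = mu
            sd[a, b, m] = sd[b, a, m] = sigma
            count[a, b, m] = count[b, a, m] = 50
    return DistanceStatistics(mean, sd, count)


def test_cutoff_from_pc_counting():
    # range 2 with significant means {4,6,8,10} and D=2: P_c = (2/2)*4 = 4,
    # so the cutoff admits all four pair types
    table = _table_with_means({2: [4.0, 6.0, 8.0, 10.0]})
    cuts = adm.range_cutoffs(table, D=2.0)
    assert cuts[2] == 10.0


def test_cutoff_capped_at_total_pairs():
    means = list(np.linspace(4, 20, 50))
    table = _table_with_means({1: means})
    cuts = adm.range_cutoffs(table, D=2.0)   # D/M = 2 -> P_c capped at 50
    assert cuts[1] == max(means)


def test_cutoff_matches_sort_oracle():
    rng = np.random.default_rng(4)
    means = list(rng.uniform(4, 25, size=100))
    table = _table_with_means({4: means})
    cuts = adm.range_cutoffs(table, D=1.0)   # P_c = 100/4 = 25
    assert cuts[4] == sorted(means)[24]


def test_empty_range_warns_and_has_no_cutoff():
    table = _table_with_means({1: [5.0]})
    with pytest.warns(UserWarning):
        cuts = adm.range_cutoffs(table, D=1.0)
    assert 2 not in cuts


def _uniform_table(mu, n_types=6, sigma=1.0):
    mean = np.full((N_AA, N_AA, DEFAULT_M_MAX + 1), np.nan)
    sd = np.zeros((N_AA, N_AA, DEFAULT_M_MAX + 1))
    count = np.zeros((N_AA, N_AA, DEFAULT_M_MAX + 1), dtype=np.int64)
    for m in range(1, DEFAULT_M_MAX + 1):
        mean[:n_types, :n_types, m] = mu
        sd[:n_types, :n_types, m] = sigma
        count[:n_types, :n_types, m] = 50
    return DistanceStatistics(mean, sd, count)


def test_map_extremes():
    seq = "A" * 30
    table = _uniform_table(10.0)
    empty = adm.build_map(seq, table, {m: 5.0 for m in range(1, 21)})
    assert empty.density == 0.0
    full = adm.build_map(seq, table, {m: 15.0 for m in range(1, 21)})
    assert full.density == 1.0


def test_homopolymer_map_matches_per_cell_oracle():
    spec = synthetic.PlantedSpec(length=40, seed=2, blocks=[(10, 30)])
    seq, table = synthetic.make_planted_stats(spec)
    cuts = adm.range_cutoffs(table, D=0.2)
    amap = adm.build_map(seq, table, cuts)
    from foldscan.structure import AA1_TO_3
    from foldscan.stats import assign_range
    for i in range(40):
        for j in range(i + 1, 40):
            m = assign_range(j - i)
            got = table.get(AA1_TO_3[seq[i]], AA1_TO_3[seq[j]], m)
            expect = got is not None and m in cuts and got[0] <= cuts[m]
            assert amap.plotted[i, j] == expect


def test_density_monotone_in_d(planted_blocks_case):
    _, seq, table = planted_blocks_case
    dens = []
    for d in [0.02, 0.05, 0.1, 0.3, 0.6, 1.0, 2.0]:
        amap = adm.build_map(seq, table, adm.range_cutoffs(table, d))
        dens.append(amap.density)
    assert all(b >= a for a, b in zip(dens, dens[1:]))


def test_calibration_against_grid_search(planted_blocks_case):
    _, seq, table = planted_blocks_case
    target = adm.DENSITY_C / len(seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d_star, amap = adm.calibrate_density(seq, table)
    grid = np.linspace(0.01, 3.0, 300)
    errs = [abs(adm.build_map(seq, table, adm.range_cutoffs(table, d)).density
                - target) for d in grid]
    assert abs(amap.density - target) <= min(errs) + 0.02


def test_degenerate_all_equal_means_warns():
    seq = "A" * 30
    table = _uniform_table(10.0)   # density can only jump 0 -> 1
    with pytest.warns(UserWarning):
        d, amap = adm.calibrate_density(seq, table, C=12.0)
    assert amap.density in (0.0, 1.0)


def _map_from_cells(n, cells):
    plotted = np.zeros((n, n), dtype=bool)
    for (i, j) in cells:
        plotted[i - 1, j - 1] = True
    return adm.AdmMap("A" * n, plotted)


def test_scan_profiles_zero_on_full_and_uniform_maps():
    n = 40
    full = _map_from_cells(n, [(i, j) for i in range(1, n) for j in range(i + 1, n + 1)])
    prof = adm.scan_profiles(full)
    assert np.allclose(prof.delta_rho_v, 0.0)
    assert np.allclose(prof.delta_rho_h, 0.0)

    rng = np.random.default_rng(0)
    p = 0.3
    cells = [(i, j) for i in range(1, n) for j in range(i + 1, n + 1)
             if rng.random() < p]
    prof = adm.scan_profiles(_map_from_cells(n, cells))
    # each part's density estimates p; allow 3 binomial standard errors
    n_cells = n * (n - 1) / 2
    for i in range(2, n - 2):
        for d in (prof.delta_rho_v[i], prof.delta_rho_h[i]):
            area = min(i * (i + 1) / 2, (n - i) * (n - i - 1) / 2)
            se = np.sqrt(p * (1 - p) / max(area, 1))
            assert abs(d) < 3 * (se + np.sqrt(p * (1 - p) / n_cells))


def test_single_block_boundary_peaks_match_exhaustive_evaluation():
    n, m, e = 30, 8, 20
    cells = [(i, j) for i in range(m, e) for j in range(i + 1, e + 1)]
    amap = _map_from_cells(n, cells)
    prof = adm.scan_profiles(amap)

    # independent exhaustive evaluation of both profiles
    plotted = {(i, j) for (i, j) in cells}
    def drho(part_a, part_b):
        if not part_a or not part_b:
            return 0.0
        return (len(plotted & set(part_a)) / len(part_a)
                - len(plotted & set(part_b)) / len(part_b))
    allcells = [(a, b) for a in range(1, n) for b in range(a + 1, n + 1)]
    for i in range(1, n + 1):
        dv = drho([c for c in allcells if c[1] <= i],
                  [c for c in allcells if c[0] <= i < c[1]])
        assert prof.delta_rho_v[i - 1] == pytest.approx(dv, abs=1e-12)
        dh = drho([c for c in allcells if c[0] >= i],
                  [c for c in allcells if c[0] < i <= c[1]])
        assert prof.delta_rho_h[i - 1] == pytest.approx(dh, abs=1e-12)

    # the horizontal profile peaks at the block start, the vertical at its end
    assert int(np.argmax(prof.delta_rho_h)) + 1 == m
    assert int(np.argmax(prof.delta_rho_v)) + 1 == e


def test_single_block_region_and_eta_hand_value():
    n, m, e = 30, 8, 20
    cells = [(i, j) for i in range(m, e) for j in range(i + 1, e + 1)]
    amap = _map_from_cells(n, cells)
    prof = adm.scan_profiles(amap)
    regions = adm.predict_regions(prof, amap, min_length=8)
    assert len(regions) == 1
    r = regions[0]
    assert abs(r.start - m) <= 2 and abs(r.end - e) <= 2
    # η is the sum of the boundary peak heights of the two profiles
    assert r.eta == pytest.approx(prof.delta_rho_h[r.start - 1]
                                  + prof.delta_rho_v[r.end - 1])


def test_empty_map_has_no_regions():
    amap = _map_from_cells(30, [])
    regions = adm.predict_regions(adm.scan_profiles(amap), amap)
    assert regions == []


def test_two_planted_blocks_recovered(planted_blocks_case):
    spec, seq, table = planted_blocks_case
    D = synthetic.planted_D(spec, table)
    amap, prof, regions = adm.analyze_sequence(seq, table, D=D)
    assert len(regions) == 2
    got = sorted([(r.start, r.end) for r in regions])
    for (gs, ge), (ts, te) in zip(got, [(5, 25), (40, 60)]):
        assert abs(gs - ts) <= 2 and abs(ge - te) <= 2


def test_region_prediction_robust_to_sparse_noise(planted_blocks_case):
    spec, seq, table = planted_blocks_case
    D = synthetic.planted_D(spec, table)
    amap = adm.build_map(seq, table, adm.range_cutoffs(table, D), D=D)
    base = adm.predict_regions(adm.scan_profiles(amap), amap)
    rng = np.random.default_rng(8)
    noisy = amap.plotted.copy()
    n = amap.n
    iu = np.triu_indices(n, k=1)
    flip = rng.random(len(iu[0])) < 0.01
    noisy[iu[0][flip], iu[1][flip]] = True
    noisy_map = adm.AdmMap(seq, noisy)
    got = adm.predict_regions(adm.scan_profiles(noisy_map), noisy_map)
    assert len(got) == len(base)
    for a, b in zip(sorted(got, key=lambda r: r.start),
                    sorted(base, key=lambda r: r.start)):
        assert abs(a.start - b.start) <= 2 and abs(a.end - b.end) <= 2


def test_terminal_thirds_plant_yields_terminal_top_regions():
    """Short-distance enrichment of the N- and C-terminal thirds puts the
    two top-η regions inside those thirds (the compact-termini picture)."""
    spec = synthetic.PlantedSpec(length=90, seed=1, blocks=[(2, 28), (62, 88)])
    seq, table = synthetic.make_planted_stats(spec)
    D = synthetic.planted_D(spec, table)
    _, _, regions = adm.analyze_sequence(seq, table, D=D)
    assert len(regions) >= 2
    top2 = sorted(regions[:2], key=lambda r: r.start)
    assert top2[0].end <= 33   # N-terminal third (plus boundary slack)
    assert top2[1].start >= 57  # C-terminal third
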