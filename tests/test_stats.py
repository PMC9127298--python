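import numpy as np
import pytest
import scipy.stats as sst

from holospect.montage import ChannelMontage
from holospect.stats import (
    AdjacencySpec, SpectralDataset, cell_ttest, chi_square_2x2, cluster_permutation,
    cohens_d, correlation_map,
)
from holospect.synthetic import simulate_spectral_dataset


def tiny_montage(n=3, spacing=10.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    return ChannelMontage(tuple(f"CH{i}" for i in range(n)), pos)


def make_ds(data, groups, montage=None):
    import pandas as pd

    montage = montage or tiny_montage(data.shape[1])
    meta = pd.DataFrame({"subject_id": [f"S{i}" for i in range(len(groups))],
                         "group": groups})
    return SpectralDataset(data=np.asarray(data, float), metadata=meta,
                           montage=montage)


# ------------------------------------------------------------------ t-tests

def test_independent_t_matches_scipy(rng):
    x = rng.normal(size=(20, 2, 3, 4))
    groups = ["A"] * 12 + ["B"] * 8
    ds = make_ds(x, groups, tiny_montage(2))
    t_map, df = cell_ttest(ds, "independent", groups=("A", "B"))
    ref = sst.ttest_ind(x[:12], x[12:], axis=0)
    assert df == 18
    assert np.allclose(t_map, ref.statistic, rtol=1e-10)


def test_paired_t_matches_scipy(rng):
    a = rng.normal(size=(15, 2, 3, 4))
    b = rng.normal(size=(15, 2, 3, 4))
    ds = make_ds(a, ["A"] * 15, tiny_montage(2))
    t_map, df = cell_ttest(ds, "paired", paired_data=(a, b))
    ref = sst.ttest_rel(a, b, axis=0)
    assert df == 14
    assert np.allclose(t_map, ref.statistic, rtol=1e-10)


def test_summary_stat_t_value():
    # two groups with known summary statistics: t = (m1-m2)/sqrt(sp2*(1/n1+1/n2))
    x1 = np.array([1.0, 2.0, 3.0, 4.0])
    x2 = np.array([3.0, 4.0, 5.0, 6.0])
    data = np.concatenate([x1, x2])[:, None, None, None]
    ds = make_ds(data, ["A"] * 4 + ["B"] * 4, tiny_montage(1))
    t_map, _ = cell_ttest(ds, "independent", groups=("A", "B"))
    expect = sst.ttest_ind(x1, x2).statistic
    assert t_map[0, 0, 0] == pytest.approx(expect)
    assert abs(t_map[0, 0, 0]) == pytest.approx(2.1908902, abs=1e-6)


# ---------------------------------------------------------------- adjacency

def test_adjacency_symmetric_and_local():
    spec = AdjacencySpec(neighbor_distance_mm=15.0)
    m = tiny_montage(3, spacing=10.0)  # chain: 0-1-2 (20 mm apart ends)
    adj = spec.build(m, n_carrier=2, n_am=2)
    n_cells = 3 * 2 * 2
    assert adj.shape == (n_cells, n_cells)
    assert (adj != adj.T).nnz == 0
    idx = np.arange(n_cells).reshape(3, 2, 2)
    # sensor neighbours: same carrier/AM cell on adjacent channels
    assert adj[idx[0, 0, 0], idx[1, 0, 0]]
    assert not adj[idx[0, 0, 0], idx[2, 0, 0]]  # 20 mm > 15 mm
    # one-axis-at-a-time: diagonal moves are not adjacent
    assert adj[idx[0, 0, 0], idx[0, 1, 0]]
    assert adj[idx[0, 0, 0], idx[0, 0, 1]]
    assert not adj[idx[0, 0, 0], idx[1, 1, 0]]
    assert not adj[idx[0, 0, 0], idx[0, 1, 1]]


def test_trend_row_adjacent_to_lowest_am():
    spec = AdjacencySpec()
    m = tiny_montage(1)
    adj = spec.build(m, n_carrier=1, n_am=3)  # AM axis: trend, am0, am1
    idx = np.arange(3)
    assert adj[idx[0], idx[1]]  # trend <-> lowest AM band
    assert not adj[idx[0], idx[2]]


# ------------------------------------------------------------- permutation

def test_identical_groups_not_significant(rng):
    base = rng.normal(size=(1, 4, 3, 3))
    data = np.repeat(base, 12, axis=0) + 0.01 * rng.normal(size=(12, 4, 3, 3))
    ds = make_ds(data, ["A"] * 6 + ["B"] * 6, tiny_montage(4))
    res = cluster_permutation(ds, "independent", groups=("A", "B"),
                              n_perm=200, seed=0)
    assert all(c.p_value > 0.05 for c in res.clusters)


def test_planted_effect_detected():
    ds = simulate_spectral_dataset(
        {"HC": 20, "PD": 20}, n_carrier_bands=4, n_am_bands=4,
        effect_cells=[(0, 1, 1), (1, 1, 1), (0, 1, 2), (1, 1, 2)],
        effect_size=1.8, effect_groups=("HC", "PD"), seed=6,
    )
    res = cluster_permutation(ds, "independent", groups=("PD", "HC"),
                              n_perm=300, seed=1)
    sig = res.significant(0.05)
    assert len(sig) >= 1
    planted = {np.ravel_multi_index(c, ds.cell_shape)
               for c in [(0, 1, 1), (1, 1, 1), (0, 1, 2), (1, 1, 2)]}
    best = min(res.clusters, key=lambda c: c.p_value)
    assert planted & set(best.cells.tolist())


def test_permutation_deterministic(rng):
    data = rng.normal(size=(16, 3, 3, 3))
    ds = make_ds(data, ["A"] * 8 + ["B"] * 8)
    r1 = cluster_permutation(ds, "independent", groups=("A", "B"),
                             n_perm=150, seed=42)
    r2 = cluster_permutation(ds, "independent", groups=("A", "B"),
                             n_perm=150, seed=42)
    assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]


def test_paired_design_sign_flips(rng):
    a = rng.normal(size=(12, 3, 3, 3))
    b = a + 1.0  # constant offset everywhere
    ds = make_ds(a, ["A"] * 12)
    res = cluster_permutation(ds, "paired", paired_data=(b, a),
                              n_perm=300, seed=3)
    assert res.significant(0.05)


# -------------------------------------------------------------- correlation

def test_correlation_map_finds_coupled_cell(rng):
    n = 40
    data = rng.normal(size=(n, 3, 3, 3))
    score = rng.normal(size=n)
    data[:, 1, 1, 1] += 1.5 * score
    ds = make_ds(data, ["A"] * n)
    r_map, res = correlation_map(ds, score, n_perm=300, seed=2)
    assert r_map[1, 1, 1] > 0.7
    best = min(res.clusters, key=lambda c: c.p_value)
    flat = np.ravel_multi_index((1, 1, 1), ds.cell_shape)
    assert flat in best.cells.tolist()
    assert best.p_value < 0.05


def test_correlation_rejects_constant_score(rng):
    ds = make_ds(rng.normal(size=(10, 3, 3, 3)), ["A"] * 10)
    with pytest.raises(ValueError):
        correlation_map(ds, np.ones(10), n_perm=50)


# ------------------------------------------------------------ demographics

def test_cohens_d_simple_cases():
    assert cohens_d(1.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)
    assert cohens_d(0.0, 2.0, 0.0, 2.0) == 0.0
    # RMS-SD denominator: |3-1| / sqrt((1+9)/2)
    assert cohens_d(3.0, 1.0, 1.0, 3.0) == pytest.approx(2.0 / np.sqrt(5.0))
    with pytest.raises(ValueError):
        cohens_d(1.0, 0.0, 0.0, 1.0)


def test_chi_square_2x2_values():
    stat, p = chi_square_2x2([[20, 0], [0, 20]])
    assert stat == pytest.approx(40.0)
    assert p < 1e-9
    ref = sst.chi2_contingency([[12, 8], [7, 13]], correction=False)
    stat2, p2 = chi_square_2x2([[12, 8], [7, 13]])
    assert stat2 == pytest.approx(ref.statistic)
    assert p2 == pytest.approx(ref.pvalue)
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [0, 0]])
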