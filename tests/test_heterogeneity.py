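import numpy as np
import pytest

from hbnet.fixtures import generate_planted_components
from hbnet.hbonds import ClassifiedNetwork, HBondCriteria, classify_pairs
from hbnet.heterogeneity import (
    find_heterogeneities,
    sh_fraction_series,
    sh_size_table,
    sh_size_table_cumulative,
    short_bond_degree_stats,
)
from hbnet.network import BondNetwork, build_bond_network


def _classified_from_edges(n_mol, edges, short_mask=None):
    """Synthetic classified network with prescribed short edges."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    short = (
        np.full(len(edges), 2, dtype=np.int8)
        if short_mask is None
        else np.where(np.asarray(short_mask), 2, 1).astype(np.int8)
    )
    net = BondNetwork(
        frame_time=0.0,
        n_mol=n_mol,
        molecule_ids=np.arange(1, n_mol + 1),
        pairs=edges,
        pair_ids=np.arange(1, n_mol + 1)[edges] if len(edges) else np.zeros((0, 2), np.int64),
        d_OO=np.full(len(edges), 2.7),
        r_cut=3.2,
    )
    return ClassifiedNetwork(
        net=net,
        labels=short,
        angle_min=np.full(len(edges), 5.0),
        donor=edges[:, 0] if len(edges) else np.zeros(0, np.int64),
        candidate_angles=np.zeros((len(edges), 4)),
        criteria=HBondCriteria(),
    )


def _chain_edges(start, length):
    return [(start + i, start + i + 1) for i in range(length - 1)]


def label_propagation_oracle(n_mol, edges, size_min=5):
    """Brute-force component finding by repeated label propagation."""
    labels = list(range(n_mol))
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            lo = min(labels[i], labels[j])
            if labels[i] != lo or labels[j] != lo:
                labels[i] = labels[j] = lo
                changed = True
    comps = {}
    for node, lab in enumerate(labels):
        comps.setdefault(lab, set()).add(node)
    # label propagation with min-label needs iteration to fixed point; the
    # while loop above already reaches it
    return sorted(
        (frozenset(c) for c in comps.values() if len(c) >= size_min),
        key=lambda c: min(c),
    )


class TestFindHeterogeneities:
    def test_path_of_four_not_counted(self):
        cn = _classified_from_edges(10, _chain_edges(0, 4))
        assert find_heterogeneities(cn).sizes == []

    def test_path_of_five_is_one_sh(self):
        cn = _classified_from_edges(10, _chain_edges(0, 5))
        d = find_heterogeneities(cn)
        assert d.sizes == [5]
        assert d.fraction_in_sh == 0.5

    def test_two_disjoint_chains(self):
        cn = _classified_from_edges(20, _chain_edges(0, 6) + _chain_edges(10, 7))
        d = find_heterogeneities(cn)
        assert sorted(d.sizes) == [6, 7]
        assert d.fraction_in_sh == pytest.approx(13 / 20)

    def test_non_short_edges_do_not_connect(self):
        edges = _chain_edges(0, 6)
        short = [True] * 4 + [False]  # last link is an ordinary H-bond
        cn = _classified_from_edges(10, edges, short)
        assert find_heterogeneities(cn).sizes == [5]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_label_propagation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        m = int(rng.integers(0, n * 2))
        edges = set()
        while len(edges) < m:
            i, j = rng.integers(0, n, size=2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        edges = sorted(edges)
        cn = _classified_from_edges(n, edges)
        detected = [frozenset(c.tolist()) for c in find_heterogeneities(cn).components]
        assert sorted(detected, key=min) == label_propagation_oracle(n, edges)

    def test_fraction_monotone_in_size_min(self):
        cn = _classified_from_edges(40, _chain_edges(0, 5) + _chain_edges(10, 9))
        fractions = [
            find_heterogeneities(cn, size_min=s).fraction_in_sh for s in (2, 5, 6, 10)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_deterministic_ordering_by_smallest_member(self):
        cn = _classified_from_edges(30, _chain_edges(20, 6) + _chain_edges(2, 5))
        d = find_heterogeneities(cn)
        assert [int(c.min()) for c in d.components] == [2, 20]


class TestPlantedComponents:
    def test_planted_sizes_recovered_exactly(self):
        frame = generate_planted_components([5, 7], 30, seed=1)
        cn = classify_pairs(frame, build_bond_network(frame))
        d = find_heterogeneities(cn)
        assert sorted(d.sizes) == [5, 7]
        assert d.fraction_in_sh == pytest.approx(12 / 30)

    def test_planted_subthreshold_group_excluded(self):
        frame = generate_planted_components([4], 20, seed=0)
        cn = classify_pairs(frame, build_bond_network(frame))
        assert find_heterogeneities(cn).sizes == []

    def test_empty_plan_yields_no_sh(self):
        frame = generate_planted_components([], 16, seed=0)
        cn = classify_pairs(frame, build_bond_network(frame))
        d = find_heterogeneities(cn)
        assert d.sizes == [] and d.fraction_in_sh == 0.0

    def test_oversized_plan_rejected(self):
        with pytest.raises(ValueError):
            generate_planted_components([10, 10], 15)


class TestSizeTable:
    def test_constant_count(self):
        cn = _classified_from_edges(40, _chain_edges(0, 5) + _chain_edges(10, 5) + _chain_edges(20, 5))
        decomps = [find_heterogeneities(cn)] * 4
        assert sh_size_table(decomps, sizes=[5])[5] == 3.0

    def test_two_frame_average(self):
        d2 = find_heterogeneities(
            _classified_from_edges(40, _chain_edges(0, 5) + _chain_edges(10, 5))
        )
        d4 = find_heterogeneities(
            _classified_from_edges(
                40,
                _chain_edges(0, 5) + _chain_edges(10, 5)
                + _chain_edges(20, 5) + _chain_edges(30, 5),
            )
        )
        assert sh_size_table([d2, d4], sizes=[5])[5] == 3.0

    def test_exact_vs_cumulative(self):
        d = find_heterogeneities(
            _classified_from_edges(40, _chain_edges(0, 5) + _chain_edges(10, 8))
        )
        exact = sh_size_table([d], sizes=[5, 8])
        cumul = sh_size_table_cumulative([d], sizes=[5, 8])
        assert exact == {5: 1.0, 8: 1.0}
        assert cumul == {5: 2.0, 8: 1.0}


class TestDegreeStats:
    def test_chain_of_five_degree_fractions(self):
        cn = _classified_from_edges(10, _chain_edges(0, 5))
        d = find_heterogeneities(cn)
        stats = short_bond_degree_stats(cn, d)
        frac = stats.degree_fractions()
        assert frac[1] == pytest.approx(0.4)
        assert frac[2] == pytest.approx(0.6)
        assert stats.mean_bonds_per_molecule == pytest.approx(2 * 4 / 10)
        assert stats.mean_bonds_per_sh_molecule == pytest.approx(2 * 4 / 5)

    def test_isolated_pair_entirely_excluded(self):
        cn = _classified_from_edges(10, [(0, 1)])
        d = find_heterogeneities(cn)
        stats = short_bond_degree_stats(cn, d)
        assert stats.n_sh_molecules == 0
        assert stats.n_short_bonds_in_sh == 0
        assert stats.mean_bonds_per_molecule == 0.0

    def test_every_chain_has_exactly_two_endpoints(self):
        cn = _classified_from_edges(30, _chain_edges(0, 6) + _chain_edges(10, 8))
        d = find_heterogeneities(cn)
        stats = short_bond_degree_stats(cn, d)
        assert stats.degree_counts[1] == 4  # two chains, two endpoints each


class TestSeries:
    def test_fraction_series_values(self):
        cn0 = _classified_from_edges(10, [])
        cn1 = _classified_from_edges(10, _chain_edges(0, 10))
        t, f = sh_fraction_series(
            [find_heterogeneities(cn0), find_heterogeneities(cn1)]
        )
        assert np.allclose(f, [0.0, 1.0])
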