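import numpy as np
import pytest

from hbnet.core import SimulationBox, reconstruct_m_site
from hbnet.energetics import (
    DEFAULT_PARAMS,
    PairEnergyTable,
    TIP4P2005Params,
    dimer_energy_surface,
    energy_histogram,
    mean_short_bond_energy,
    pair_energies,
    pair_interaction_energy,
)
from hbnet.fixtures import generate_dimer
from hbnet.hbonds import classify_pairs
from hbnet.network import build_bond_network

from conftest import random_rigid_frame


def site_sum_oracle(a, b, box, p=DEFAULT_PARAMS):
    """Independent brute-force enumeration of the 1 LJ + 9 Coulomb terms."""
    from hbnet.core import minimum_image_displacement

    roff = minimum_image_displacement(a.O, b.O, box)
    shift = roff - (b.O - a.O)
    Ma = reconstruct_m_site(a, p.geometry)
    Mb = reconstruct_m_site(b, p.geometry) + shift
    sa = [(a.H1, p.q_H), (a.H2, p.q_H), (Ma, p.q_M)]
    sb = [(b.H1 + shift, p.q_H), (b.H2 + shift, p.q_H), (Mb, p.q_M)]
    u = 0.0
    for ra, qa in sa:
        for rb, qb in sb:
            u += p.k_e * qa * qb / np.linalg.norm(ra - rb)
    r = np.linalg.norm(roff)
    x6 = (p.sigma_OO / r) ** 6
    return u + 4.0 * p.epsilon_OO * (x6 * x6 - x6)


class TestPairEnergy:
    def test_matches_site_enumeration_oracle_on_random_dimers(self):
        frame = random_rigid_frame(200, 40.0, seed=21, min_sep=2.4)
        net = build_bond_network(frame, r_cut=6.0)
        for i, j in net.pairs[:100]:
            a, b = frame.molecule(int(i)), frame.molecule(int(j))
            assert pair_interaction_energy(a, b, frame.box) == pytest.approx(
                site_sum_oracle(a, b, frame.box), abs=1e-10
            )

    def test_vectorized_equals_scalar(self):
        frame = random_rigid_frame(100, 30.0, seed=22, min_sep=2.4).with_m_sites()
        net = build_bond_network(frame)
        vec = pair_energies(frame, net.pairs)
        for k, (i, j) in enumerate(net.pairs):
            scal = pair_interaction_energy(
                frame.molecule(int(i)), frame.molecule(int(j)), frame.box
            )
            assert vec[k] == pytest.approx(scal, abs=1e-10)

    def test_symmetry(self):
        frame = generate_dimer(2.9, 15.0)
        a, b = frame.molecule(0), frame.molecule(1)
        assert pair_interaction_energy(a, b, frame.box) == pytest.approx(
            pair_interaction_energy(b, a, frame.box), abs=1e-12
        )

    def test_vanishes_at_large_separation(self):
        frame = generate_dimer(50.0, 0.0, box_length=200.0)
        u = pair_interaction_energy(frame.molecule(0), frame.molecule(1), frame.box)
        assert abs(u) < 0.01

    def test_monotone_decay_of_magnitude(self):
        def u(R):
            f = generate_dimer(R, 0.0, box_length=250.0)
            return pair_interaction_energy(f.molecule(0), f.molecule(1), f.box)

        assert abs(u(20.0)) < abs(u(10.0)) < abs(u(6.0))

    def test_rigid_cotransformation_invariance(self):
        frame = generate_dimer(2.9, 20.0)
        u0 = pair_interaction_energy(frame.molecule(0), frame.molecule(1), frame.box)
        rng = np.random.default_rng(1)
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = np.array([5.0, -3.0, 7.0])
        a, b = frame.molecule(0), frame.molecule(1)
        for m in (a, b):
            m.O = R @ m.O + t
            m.H1 = R @ m.H1 + t
            m.H2 = R @ m.H2 + t
            m.M = None
        u1 = pair_interaction_energy(a, b, frame.box)
        assert u1 == pytest.approx(u0, abs=1e-9)

    def test_overlapping_sites_rejected(self):
        frame = generate_dimer(2.9, 0.0)
        a = frame.molecule(0)
        with pytest.raises(ValueError, match="overlap"):
            pair_interaction_energy(a, a, frame.box)

    def test_charge_neutrality_enforced(self):
        with pytest.raises(ValueError, match="neutrality"):
            TIP4P2005Params(q_H=0.5, q_M=-1.1128)


class TestDimerSurface:
    @pytest.fixture(scope="class")
    def surface(self):
        return dimer_energy_surface(
            np.arange(2.5, 6.01, 0.05), np.arange(0.0, 41.0, 5.0)
        )

    def test_minimum_depth_nonincreasing_with_angle(self, surface):
        assert np.all(np.diff(surface.min_U) >= -1e-9)

    def test_deep_minimum_below_three_for_hbond_angles(self, surface):
        sel = surface.angle_grid < 30.0
        assert np.all(surface.min_U[sel] < -3.0)

    def test_asymptotic_zero_at_large_separation(self):
        surf = dimer_energy_surface([25.0], [0.0, 30.0])
        assert np.all(np.abs(surf.U) < 0.05)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            dimer_energy_surface([], [0.0])


class TestEnergyHistogram:
    def _tables(self, frames):
        out = []
        for f in frames:
            net = build_bond_network(f)
            cn = classify_pairs(f, net)
            out.append(PairEnergyTable.from_classified(f, cn))
        return out

    def test_single_pair_bin_placement(self):
        # construct a table directly with a known energy
        t = PairEnergyTable(0.0, 2, np.array([[0, 1]]), np.array([-5.23]), np.array([1]))
        hist = energy_histogram([t])
        k = int(np.flatnonzero(hist.values)[0])
        assert hist.edges[k] == pytest.approx(-5.3)
        assert hist.edges[k + 1] == pytest.approx(-5.2)

    def test_split_conservation(self, liquid_frames):
        frames, _ = liquid_frames
        tables = self._tables(frames)
        total = energy_histogram(tables, split="all").total()
        hb = energy_histogram(tables, split="hbonded").total()
        nb = energy_histogram(tables, split="nonbonded").total()
        assert hb + nb == pytest.approx(total)

    def test_unknown_keys_rejected(self, liquid_frames):
        frames, _ = liquid_frames
        tables = self._tables(frames[:1])
        with pytest.raises(ValueError, match="split"):
            energy_histogram(tables, split="bogus")
        with pytest.raises(ValueError, match="normalization"):
            energy_histogram(tables, normalization="bogus")

    def test_ice_pair_energies_in_crystalline_interval(self, ice_frame):
        """Every nearest-neighbor pair of proton-disordered ice Ih has
        an interaction energy in the narrow [-7, -5] kcal/mol band
        characteristic of the crystalline phases."""
        tables = self._tables([ice_frame])
        U = tables[0].U
        assert np.all(U > -7.0) and np.all(U < -5.0)


class TestMeanShortBondEnergy:
    def test_constant_energies(self):
        t = PairEnergyTable(
            0.0, 12, np.array([[i, i + 1] for i in range(6)]),
            np.full(6, -6.0), np.full(6, 2),
        )
        assert mean_short_bond_energy([t])[0] == pytest.approx(-6.0)

    def test_two_bond_average(self):
        t = PairEnergyTable(
            0.0, 4, np.array([[0, 1], [2, 3]]), np.array([-5.0, -7.0]), np.array([2, 2])
        )
        assert mean_short_bond_energy([t])[0] == pytest.approx(-6.0)

    def test_frame_without_short_bonds_is_missing(self):
        t = PairEnergyTable(0.0, 2, np.array([[0, 1]]), np.array([-5.0]), np.array([1]))
        assert np.isnan(mean_short_bond_energy([t])[0])
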