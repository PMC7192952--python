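import math

import numpy as np
import pytest

from hbnet.core import Frame, SimulationBox, WaterMolecule
from hbnet.fixtures import generate_dimer
from hbnet.hbonds import (
    HBondCriteria,
    LABEL_HBOND,
    LABEL_SHORT,
    angle_histogram,
    classify_pair,
    classify_pairs,
    hbond_length_histogram,
    hbond_stats,
    hoo_angle,
)
from hbnet.network import build_bond_network

from conftest import random_rigid_frame


def _mol(mid, O, H1, H2):
    return WaterMolecule(mid, np.array(O, float), np.array(H1, float), np.array(H2, float))


BIG_BOX = SimulationBox(np.full(3, 100.0))


class TestHooAngle:
    def test_collinear_hydrogen_gives_zero(self):
        donor = _mol(1, [0, 0, 0], [0.9572, 0, 0], [-0.24, 0.927, 0])
        acceptor = _mol(2, [2.8, 0, 0], [3.7, 0.3, 0], [2.5, 0.9, 0])
        angle, hid = hoo_angle(donor, acceptor, BIG_BOX)
        assert angle == pytest.approx(0.0, abs=1e-9)
        assert hid == 1

    def test_perpendicular_hydrogen_gives_ninety(self):
        donor = _mol(1, [0, 0, 0], [0, 0, 0.9572], [0, 0.927, -0.24])
        acceptor = _mol(2, [2.8, 0, 0], [3.7, 0.3, 0], [2.5, 0.9, 0])
        angle, _ = hoo_angle(donor, acceptor, BIG_BOX)
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_coincident_oxygens_rejected(self):
        a = _mol(1, [0, 0, 0], [0.9572, 0, 0], [-0.24, 0.927, 0])
        b = _mol(2, [0, 0, 0], [0.9572, 0, 0], [-0.24, 0.927, 0])
        with pytest.raises(ValueError, match="coincident"):
            hoo_angle(a, b, BIG_BOX)

    @pytest.mark.parametrize("angle", [0.0, 7.5, 17.0, 29.999, 45.0])
    def test_dimer_generator_construction_identity(self, angle):
        frame = generate_dimer(2.8, angle)
        measured, _ = hoo_angle(frame.molecule(0), frame.molecule(1), frame.box)
        assert measured == pytest.approx(angle, abs=1e-6)
        d = np.linalg.norm(frame.O[1] - frame.O[0])
        assert d == pytest.approx(2.8, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "d,angle,expected",
        [
            (2.70, 10.0, "short_hbond"),
            (3.00, 25.0, "hbond"),
            (3.00, 35.0, "nonbonded"),
            (2.70, 35.0, "nonbonded"),  # short distance but failed angle
            (2.76, 10.0, "hbond"),  # boundary distance is not short (strict <)
        ],
    )
    def test_geometric_criteria(self, d, angle, expected):
        frame = generate_dimer(d, angle)
        net = build_bond_network(frame)
        label, angle_min, _ = classify_pair(frame, net, 0)
        assert label == expected
        assert angle_min == pytest.approx(angle, abs=1e-6)

    def test_short_subset_of_hbond_subset_of_pairs(self, liquid_frames):
        frames, _ = liquid_frames
        for frame in frames:
            net = build_bond_network(frame)
            cn = classify_pairs(frame, net)
            assert cn.n_short <= cn.n_hbonds <= net.n_pairs
            assert np.all(cn.short_mask <= cn.hbond_mask)

    def test_angle_invariant_under_rigid_transformation(self):
        """Rotating and translating a whole cluster leaves the
        pair angles unchanged."""
        frame = random_rigid_frame(40, 12.0, seed=13)
        big = SimulationBox(np.full(3, 200.0))
        loose = Frame(0.0, big, frame.molecule_ids, frame.O, frame.H1, frame.H2)
        rng = np.random.default_rng(2)
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
        t = np.array([30.0, 40.0, 50.0])
        moved = Frame(
            0.0, big, loose.molecule_ids,
            loose.O @ R.T + t, loose.H1 @ R.T + t, loose.H2 @ R.T + t,
        )
        cn0 = classify_pairs(loose, build_bond_network(loose))
        cn1 = classify_pairs(moved, build_bond_network(moved))
        assert np.array_equal(cn0.net.pairs, cn1.net.pairs)
        assert np.allclose(cn0.angle_min, cn1.angle_min, atol=1e-8)
        assert np.array_equal(cn0.labels, cn1.labels)

    def test_ice_angles_within_ten_degrees(self, ice_frame):
        net = build_bond_network(ice_frame)
        cn = classify_pairs(ice_frame, net)
        assert cn.angle_min.max() <= 10.0
        assert cn.n_hbonds == net.n_pairs


class TestStats:
    def test_ice_every_molecule_has_four_hbonds(self, ice_frame):
        net = build_bond_network(ice_frame)
        stats = hbond_stats([classify_pairs(ice_frame, net)])[0]
        assert stats.hbonds_per_molecule == 2.0
        frac = stats.degree_fractions()
        assert frac[4] == 1.0
        assert np.isclose(frac.sum(), 1.0)

    def test_single_dimer_both_degree_one(self):
        frame = generate_dimer(3.0, 10.0)
        stats = hbond_stats([classify_pairs(frame, build_bond_network(frame))])[0]
        assert np.array_equal(stats.degree_counts, [0, 2])

    def test_degree_fractions_sum_to_one_on_liquid(self, liquid_frames):
        frames, _ = liquid_frames
        for frame in frames:
            stats = hbond_stats([classify_pairs(frame, build_bond_network(frame))])[0]
            assert np.isclose(stats.degree_fractions().sum(), 1.0)
            assert 0.0 <= stats.hbonds_per_pair <= 1.0


class TestHistograms:
    def test_all_zero_angles_fill_first_bin(self):
        frame = generate_dimer(2.8, 0.0)
        cn = classify_pairs(frame, build_bond_network(frame))
        hist = angle_histogram([cn])
        assert hist.values[0] == 1.0
        assert hist.total() == 1.0

    def test_angle_mass_equals_mean_pair_count(self, liquid_frames):
        frames, _ = liquid_frames
        cns = [classify_pairs(f, build_bond_network(f)) for f in frames]
        hist = angle_histogram(cns)
        assert np.isclose(hist.total(), np.mean([cn.net.n_pairs for cn in cns]))

    def test_all_candidate_histogram_has_four_angles_per_pair(self, ice_frame):
        cn = classify_pairs(ice_frame, build_bond_network(ice_frame))
        hist = angle_histogram([cn], all_candidates=True)
        assert np.isclose(hist.total(), 4 * cn.net.n_pairs)

    def test_hbond_length_restricted_to_bonded_pairs(self):
        nonbonded = generate_dimer(3.0, 60.0)
        cn = classify_pairs(nonbonded, build_bond_network(nonbonded))
        assert hbond_length_histogram([cn]).total() == 0.0

    def test_hbond_length_mass_equals_mean_in_range_hbond_count(self, liquid_frames):
        frames, _ = liquid_frames
        cns = [classify_pairs(f, build_bond_network(f)) for f in frames]
        hist = hbond_length_histogram(cns)
        expected = np.mean(
            [int((cn.net.d_OO[cn.hbond_mask] >= hist.edges[0]).sum()) for cn in cns]
        )
        assert np.isclose(hist.total(), expected)


class TestCriteriaValidation:
    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            HBondCriteria(r_max=3.2, r_short=3.3)
        with pytest.raises(ValueError):
            HBondCriteria(angle_max=0.0)

    def test_short_fraction_recovery_on_planted_fixture(self, liquid_frames):
        """Generator parameter recovery: realized short-bond fraction
        is within the +/-2% contract of the requested target."""
        frames, meta = liquid_frames
        target = meta["target_short_fraction"]
        for frame in frames:
            net = build_bond_network(frame)
            cn = classify_pairs(frame, net)
            assert cn.n_short / net.n_pairs == pytest.approx(target, abs=0.02)
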