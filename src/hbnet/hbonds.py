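"""Geometric H-bond classification of bond-network pairs.

A network pair is an H-bond when at least one of its four
(donor molecule, covalent hydrogen) candidates has an H-O...O angle --
the angle at the donor oxygen between the covalent O-H vector and the
donor-to-acceptor O...O vector -- below ``angle_max`` (default 30 deg).
H-bonds shorter than ``r_short`` (default 2.76 A, the nearest-neighbor
O...O distance of ice Ih) are *short* H-bonds, the building blocks of
structural heterogeneities.

Pairs are classified, not directed bonds: a pair contributes one
H-bond even if several candidates pass the angle criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Frame, SimulationBox, WaterMolecule, minimum_image_displacement
from .network import BondNetwork, Histogram, histogram_over_frames

__all__ = [
    "HBondCriteria",
    "ClassifiedNetwork",
    "HBondFrameStats",
    "LABEL_NONBONDED",
    "LABEL_HBOND",
    "LABEL_SHORT",
    "hoo_angle",
    "classify_pairs",
    "classify_pair",
    "angle_histogram",
    "hbond_length_histogram",
    "hbond_stats",
]

LABEL_NONBONDED = 0
LABEL_HBOND = 1
LABEL_SHORT = 2


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: R_OO < r_max and angle(H-O...O) < angle_max;
    short additionally requires R_OO < r_short."""

    r_max: float = 3.2
    angle_max: float = 30.0
    r_short: float = 2.76

    def __post_init__(self) -> None:
        if not (0.0 < self.r_short < self.r_max):
            raise ValueError("need 0 < r_short < r_max")
        if not (0.0 < self.angle_max < 180.0):
            raise ValueError("angle_max must be in (0, 180) degrees")


def hoo_angle(
    donor: WaterMolecule, acceptor: WaterMolecule, box: SimulationBox
) -> tuple[float, int]:
    """Minimum H-O...O angle of a directed donor->acceptor pair.

    Returns ``(angle_min in degrees, donor hydrogen index 1 or 2)``.
    """
    r = minimum_image_displacement(donor.O, acceptor.O, box)
    rn = np.linalg.norm(r)
    if rn < 1e-8:
        raise ValueError("coincident oxygens: H-O...O angle undefined")
    angles = []
    for h in (donor.H1, donor.H2):
        v = minimum_image_displacement(donor.O, h, box)
        c = float(np.dot(v, r) / (np.linalg.norm(v) * rn))
        angles.append(float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))))
    k = int(np.argmin(angles))
    return angles[k], k + 1


@dataclass
class ClassifiedNetwork:
    """Per-pair labels and mutual-orientation angles for one frame.

    ``angle_min`` is the minimum H-O...O angle over the four
    (donor, hydrogen) candidates of each pair; ``donor`` the index of
    the molecule achieving it; ``candidate_angles`` the full (P, 4)
    matrix, columns (i:H1, i:H2, j:H1, j:H2).
    """

    net: BondNetwork
    labels: np.ndarray  # (P,) int8
    angle_min: np.ndarray  # (P,)
    donor: np.ndarray  # (P,) molecule index of the best donor
    candidate_angles: np.ndarray  # (P, 4)
    criteria: HBondCriteria

    @property
    def hbond_mask(self) -> np.ndarray:
        return self.labels >= LABEL_HBOND

    @property
    def short_mask(self) -> np.ndarray:
        return self.labels == LABEL_SHORT

    @property
    def n_hbonds(self) -> int:
        return int(self.hbond_mask.sum())

    @property
    def n_short(self) -> int:
        return int(self.short_mask.sum())

    @property
    def n_short_rejected_by_angle(self) -> int:
        """Diagnostic: pairs under r_short failing the angle criterion."""
        return int(((self.net.d_OO < self.criteria.r_short) & ~self.hbond_mask).sum())

    def hbond_degrees(self) -> np.ndarray:
        """Per-molecule H-bond counts (index order)."""
        deg = np.zeros(self.net.n_mol, dtype=np.int64)
        p = self.net.pairs[self.hbond_mask]
        if len(p):
            np.add.at(deg, p[:, 0], 1)
            np.add.at(deg, p[:, 1], 1)
        return deg


def _candidate_angle_matrix(frame: Frame, net: BondNetwork) -> np.ndarray:
    """(P, 4) H-O...O candidate angles, columns (i:H1, i:H2, j:H1, j:H2)."""
    P = net.n_pairs
    if P == 0:
        return np.zeros((0, 4))
    i, j = net.pairs[:, 0], net.pairs[:, 1]
    box = frame.box
    r_ij = minimum_image_displacement(frame.O[i], frame.O[j], box)  # donor i -> acceptor j
    rn = np.linalg.norm(r_ij, axis=1)
    if np.any(rn < 1e-8):
        raise ValueError("coincident oxygens in bond network")
    out = np.empty((P, 4))
    col = 0
    for donor_idx, sign in ((i, 1.0), (j, -1.0)):
        r = sign * r_ij
        for H in (frame.H1, frame.H2):
            v = minimum_image_displacement(frame.O[donor_idx], H[donor_idx], box)
            c = np.einsum("ij,ij->i", v, r) / (np.linalg.norm(v, axis=1) * rn)
            out[:, col] = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
            col += 1
    return out


def classify_pairs(
    frame: Frame, net: BondNetwork, crit: HBondCriteria = HBondCriteria()
) -> ClassifiedNetwork:
    """Label every network pair as short H-bond, H-bond or non-bonded."""
    ang = _candidate_angle_matrix(frame, net)
    if net.n_pairs:
        best = np.argmin(ang, axis=1)
        angle_min = ang[np.arange(net.n_pairs), best]
        donor = np.where(best < 2, net.pairs[:, 0], net.pairs[:, 1])
    else:
        angle_min = np.zeros(0)
        donor = np.zeros(0, dtype=np.int64)
    labels = np.zeros(net.n_pairs, dtype=np.int8)
    is_hb = (angle_min < crit.angle_max) & (net.d_OO < crit.r_max)
    labels[is_hb] = LABEL_HBOND
    labels[is_hb & (net.d_OO < crit.r_short)] = LABEL_SHORT
    return ClassifiedNetwork(net, labels, angle_min, donor, ang, crit)


def classify_pair(
    frame: Frame, net: BondNetwork, pair_index: int, crit: HBondCriteria = HBondCriteria()
) -> tuple[str, float, int]:
    """Classify one network pair; returns (label, angle_min, donor index)."""
    cn = classify_pairs(frame, net, crit)
    name = {LABEL_NONBONDED: "nonbonded", LABEL_HBOND: "hbond", LABEL_SHORT: "short_hbond"}
    return (
        name[int(cn.labels[pair_index])],
        float(cn.angle_min[pair_index]),
        int(cn.donor[pair_index]),
    )


def angle_histogram(
    classified: Sequence[ClassifiedNetwork],
    bin_width: float = 1.0,
    all_candidates: bool = False,
) -> Histogram:
    """Time-averaged distribution of mutual-orientation angles (1 deg step).

    By default one angle per pair (the classification minimum); with
    ``all_candidates`` all four donor-hydrogen angles are histogrammed.
    """
    if len(classified) == 0:
        raise ValueError("need at least one classified frame")
    samples = [
        cn.candidate_angles.ravel() if all_candidates else cn.angle_min for cn in classified
    ]
    return histogram_over_frames(samples, bin_width, 0.0, 180.0, "raw")


def hbond_length_histogram(
    classified: Sequence[ClassifiedNetwork],
    bin_width: float = 0.01,
    lo: float = 2.2,
) -> Histogram:
    """O...O length distribution restricted to H-bonded pairs."""
    if len(classified) == 0:
        raise ValueError("need at least one classified frame")
    hi = max(cn.net.r_cut for cn in classified)
    samples = [cn.net.d_OO[cn.hbond_mask] for cn in classified]
    return histogram_over_frames(samples, bin_width, lo, hi, "raw")


@dataclass
class HBondFrameStats:
    """Per-frame H-bond network statistics."""

    time: float
    n_mol: int
    n_pairs: int
    n_hbonds: int
    n_short: int
    degree_counts: np.ndarray  # degree_counts[k] = molecules with k H-bonds

    @property
    def hbonds_per_molecule(self) -> float:
        return self.n_hbonds / self.n_mol

    @property
    def hbonds_per_pair(self) -> float:
        return self.n_hbonds / self.n_pairs if self.n_pairs else 0.0

    def degree_fractions(self, max_degree: int = 5) -> np.ndarray:
        """Fractions of molecules with 0..max_degree-1 and >= max_degree
        ('5+' bucket by default) H-bonds; sums to 1."""
        frac = np.zeros(max_degree + 1)
        for k, c in enumerate(self.degree_counts):
            frac[min(k, max_degree)] += c
        return frac / self.n_mol


def hbond_stats(classified: Sequence[ClassifiedNetwork]) -> list[HBondFrameStats]:
    """Per-frame counts and per-molecule H-bond degree distributions."""
    out = []
    for cn in classified:
        deg = cn.hbond_degrees()
        out.append(
            HBondFrameStats(
                time=cn.net.frame_time,
                n_mol=cn.net.n_mol,
                n_pairs=cn.net.n_pairs,
                n_hbonds=cn.n_hbonds,
                n_short=cn.n_short,
                degree_counts=np.bincount(deg, minlength=1),
            )
        )
    return out
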