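"""Per-frame O...O bond-network construction and structural statistics.

The bond network (BN) of a frame is the graph whose edges are all
unordered oxygen pairs closer than a cutoff (default 3.2 A, strict
inequality) under the minimum-image convention.  Every molecule of
liquid water belongs to this network; its per-molecule degree is the
coordination number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, SimulationBox, minimum_image_displacement

__all__ = [
    "BondNetwork",
    "CoordinationProfile",
    "build_bond_network",
    "build_bond_network_brute_force",
    "coordination_profile",
    "distance_histogram",
    "assert_spanning",
    "DEFAULT_R_CUT",
]

DEFAULT_R_CUT = 3.2  # A


@dataclass
class BondNetwork:
    """O...O pairs of one frame with their minimum-image distances.

    ``pairs`` holds index pairs (i, j), i < j, into the frame's arrays;
    ``pair_ids`` the corresponding molecule ids; ``d_OO`` the distances.
    """

    frame_time: float
    n_mol: int
    molecule_ids: np.ndarray  # (N,) frame molecule ids, index order
    pairs: np.ndarray  # (P, 2) int, row-wise i < j, lexicographically sorted
    pair_ids: np.ndarray  # (P, 2) molecule ids
    d_OO: np.ndarray  # (P,)
    r_cut: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def degrees(self) -> np.ndarray:
        """Coordination number of every molecule (index order)."""
        deg = np.zeros(self.n_mol, dtype=np.int64)
        if self.n_pairs:
            np.add.at(deg, self.pairs[:, 0], 1)
            np.add.at(deg, self.pairs[:, 1], 1)
        return deg


def _pair_distances(frame: Frame, pairs: np.ndarray) -> np.ndarray:
    if len(pairs) == 0:
        return np.zeros(0)
    disp = minimum_image_displacement(frame.O[pairs[:, 0]], frame.O[pairs[:, 1]], frame.box)
    return np.linalg.norm(disp, axis=1)


def _sorted_network(frame: Frame, pairs: np.ndarray, d: np.ndarray, r_cut: float) -> BondNetwork:
    if len(pairs):
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs, d = pairs[order], d[order]
    return BondNetwork(
        frame_time=frame.time,
        n_mol=frame.n_mol,
        molecule_ids=frame.molecule_ids.copy(),
        pairs=pairs.astype(np.int64).reshape(-1, 2),
        pair_ids=frame.molecule_ids[pairs].reshape(-1, 2) if len(pairs) else np.zeros((0, 2), np.int64),
        d_OO=d,
        r_cut=r_cut,
    )


def build_bond_network(frame: Frame, r_cut: float = DEFAULT_R_CUT) -> BondNetwork:
    """All unordered O-O pairs with minimum-image distance < ``r_cut``.

    Neighbor candidates come from a periodic k-d tree (cell-list
    equivalent); distances are then recomputed with the package's own
    minimum image and filtered strictly, so the result is exactly the
    pair set of the O(N^2) scan.
    """
    frame.box.check_cutoff(r_cut)
    L = frame.box.lengths
    # cKDTree with boxsize needs coordinates in [0, L)
    pos = np.mod(frame.O - frame.box.origin, L)
    pos = np.where(pos >= L, 0.0, pos)  # guard against round-up at the boundary
    tree = cKDTree(pos, boxsize=L)
    cand = tree.query_pairs(r=r_cut * (1.0 + 1e-9), output_type="ndarray")
    cand = np.sort(cand, axis=1) if len(cand) else cand.reshape(0, 2)
    d = _pair_distances(frame, cand)
    keep = d < r_cut
    return _sorted_network(frame, cand[keep], d[keep], r_cut)


def build_bond_network_brute_force(frame: Frame, r_cut: float = DEFAULT_R_CUT) -> BondNetwork:
    """Reference O(N^2) all-pairs scan (identical contract)."""
    frame.box.check_cutoff(r_cut)
    n = frame.n_mol
    iu, ju = np.triu_indices(n, k=1)
    pairs = np.column_stack([iu, ju])
    d = _pair_distances(frame, pairs)
    keep = d < r_cut
    return _sorted_network(frame, pairs[keep], d[keep], r_cut)


@dataclass
class CoordinationProfile:
    """Distribution of per-molecule coordination numbers for one frame."""

    counts: np.ndarray  # counts[k] = number of molecules with coordination k
    fractions: np.ndarray
    n_mean: float  # n(R) = 2 N_OO / N_mol
    n_mol: int

    def fraction(self, k: int) -> float:
        return float(self.fractions[k]) if k < len(self.fractions) else 0.0


def coordination_profile(net: BondNetwork) -> CoordinationProfile:
    """Exact per-molecule coordination counts, including coordination 0."""
    deg = net.degrees()
    counts = np.bincount(deg, minlength=1)
    fractions = counts / net.n_mol
    n_mean = 2.0 * net.n_pairs / net.n_mol
    assert int((np.arange(len(counts)) * counts).sum()) == 2 * net.n_pairs
    return CoordinationProfile(counts, fractions, n_mean, net.n_mol)


@dataclass
class Histogram:
    """Left-closed right-open binned distribution with fixed edges."""

    edges: np.ndarray  # (B+1,)
    values: np.ndarray  # (B,)
    normalization: str

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def total(self) -> float:
        return float(self.values.sum())


def _anchored_edges(lo: float, hi: float, bin_width: float) -> np.ndarray:
    """Bin edges anchored at 0.0 so e.g. 2.76 falls in [2.76, 2.77)."""
    i0 = int(np.floor(lo / bin_width + 1e-9))
    i1 = int(np.ceil(hi / bin_width - 1e-9))
    return np.arange(i0, i1 + 1) * bin_width


def histogram_over_frames(
    samples_per_frame: Sequence[np.ndarray],
    bin_width: float,
    lo: float,
    hi: float,
    normalization: str = "raw",
) -> Histogram:
    """Time-averaged histogram: mean over frames of per-frame counts.

    ``raw`` sums to the mean per-frame sample count; ``per_frame_pairs``
    divides each frame's counts by that frame's sample count (empty
    frames contribute zeros).
    """
    if len(samples_per_frame) == 0:
        raise ValueError("need at least one frame to histogram")
    if normalization not in ("raw", "per_frame_pairs"):
        raise ValueError(f"unknown normalization {normalization!r}")
    edges = _anchored_edges(lo, hi, bin_width)
    acc = np.zeros(len(edges) - 1)
    for s in samples_per_frame:
        counts, _ = np.histogram(s, bins=edges)
        # np.histogram closes the last bin on the right; undo that
        if len(s) and np.any(s == edges[-1]):
            counts[-1] -= int(np.sum(s == edges[-1]))
        if normalization == "per_frame_pairs":
            counts = counts / len(s) if len(s) else counts.astype(float)
        acc = acc + counts
    return Histogram(edges, acc / len(samples_per_frame), normalization)


def distance_histogram(
    nets: Sequence[BondNetwork],
    bin_width: float = 0.01,
    normalization: str = "raw",
    lo: float = 2.2,
) -> Histogram:
    """Time-averaged distribution of O...O pair lengths (default 0.01 A step)."""
    if len(nets) == 0:
        raise ValueError("need at least one bond network")
    hi = max(net.r_cut for net in nets)
    return histogram_over_frames([net.d_OO for net in nets], bin_width, lo, hi, normalization)


def assert_spanning(net: BondNetwork) -> tuple[bool, list[int]]:
    """True iff no molecule is isolated (coordination >= 1 everywhere).

    Returns the list of isolated molecule ids.  This checks the absence
    of detached molecules, not single-component connectivity.
    """
    deg = net.degrees()
    isolated = np.flatnonzero(deg == 0)
    return len(isolated) == 0, net.molecule_ids[isolated].tolist()
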