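"""Detection and statistics of structural heterogeneities (SHs).

An SH is a connected component, of at least ``size_min`` molecules
(default 5), of the graph whose edges are the *short* H-bonds of one
frame (O...O < 2.76 A and H-O...O angle < 30 deg).  Groups of 2-4
molecules are not counted.  Edges are already periodic-image resolved,
so a component may wrap the box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .hbonds import ClassifiedNetwork

__all__ = [
    "SHDecomposition",
    "ShortBondDegreeStats",
    "find_heterogeneities",
    "sh_size_table",
    "sh_size_table_cumulative",
    "sh_fraction_series",
    "short_bond_degree_stats",
    "DEFAULT_SIZE_MIN",
    "TABLE_SIZES",
]

DEFAULT_SIZE_MIN = 5
#: Component sizes reported in the time-averaged SH size table.
TABLE_SIZES = (5, 8, 10, 15, 20, 25, 30, 40, 50, 75, 100)


@dataclass
class SHDecomposition:
    """Connected components of size >= size_min of one frame's
    short-H-bond graph."""

    frame_time: float
    n_mol: int
    size_min: int
    components: list[np.ndarray]  # molecule *indices*, each sorted; ordered by min id
    component_ids: list[np.ndarray]  # matching molecule ids
    short_edges: np.ndarray  # (E, 2) all short-bond index pairs of the frame

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    @property
    def n_molecules_in_sh(self) -> int:
        return int(sum(self.sizes))

    @property
    def fraction_in_sh(self) -> float:
        return self.n_molecules_in_sh / self.n_mol

    def size_counts(self) -> dict[int, int]:
        """N_S: number of components of each exact size S."""
        out: dict[int, int] = {}
        for s in self.sizes:
            out[s] = out.get(s, 0) + 1
        return out

    def member_index_set(self) -> frozenset[int]:
        if not self.components:
            return frozenset()
        return frozenset(np.concatenate(self.components).tolist())


def find_heterogeneities(
    classified: ClassifiedNetwork, size_min: int = DEFAULT_SIZE_MIN
) -> SHDecomposition:
    """Connected components of the short-H-bond graph, keeping those
    with >= size_min molecules; deterministic ordering by smallest
    member molecule id."""
    net = classified.net
    edges = net.pairs[classified.short_mask]
    n = net.n_mol
    if len(edges):
        adj = coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    comps: list[np.ndarray] = []
    order = np.argsort(labels, kind="stable")
    boundaries = np.flatnonzero(np.diff(labels[order])) + 1
    for group in np.split(order, boundaries):
        if len(group) >= size_min:
            comps.append(np.sort(group))
    comps.sort(key=lambda c: int(net.molecule_ids[c].min()))
    return SHDecomposition(
        frame_time=net.frame_time,
        n_mol=n,
        size_min=size_min,
        components=comps,
        component_ids=[net.molecule_ids[c] for c in comps],
        short_edges=edges,
    )


def sh_size_table(
    decomps: Sequence[SHDecomposition], sizes: Sequence[int] = TABLE_SIZES
) -> dict[int, float]:
    """Time-averaged number of SHs of each exact size S:
    (1/n) * sum_t N_S(t) over the n analyzed frames."""
    if len(decomps) == 0:
        raise ValueError("need at least one frame")
    acc = {int(s): 0.0 for s in sizes}
    for d in decomps:
        counts = d.size_counts()
        for s in acc:
            acc[s] += counts.get(s, 0)
    return {s: v / len(decomps) for s, v in acc.items()}


def sh_size_table_cumulative(
    decomps: Sequence[SHDecomposition], sizes: Sequence[int] = TABLE_SIZES
) -> dict[int, float]:
    """Cumulative variant: time-averaged number of SHs of size >= S."""
    if len(decomps) == 0:
        raise ValueError("need at least one frame")
    acc = {int(s): 0.0 for s in sizes}
    for d in decomps:
        for s in acc:
            acc[s] += sum(1 for x in d.sizes if x >= s)
    return {s: v / len(decomps) for s, v in acc.items()}


def sh_fraction_series(
    decomps: Sequence[SHDecomposition],
) -> tuple[np.ndarray, np.ndarray]:
    """(times, fraction of molecules belonging to an SH) per frame."""
    t = np.array([d.frame_time for d in decomps])
    f = np.array([d.fraction_in_sh for d in decomps])
    return t, f


@dataclass
class ShortBondDegreeStats:
    """Short-H-bond participation of molecules inside SHs, one frame."""

    frame_time: float
    n_mol: int
    n_sh_molecules: int
    n_short_bonds_in_sh: int
    degree_counts: np.ndarray  # counts over SH molecules; index = degree

    @property
    def mean_bonds_per_molecule(self) -> float:
        """Short bonds in SHs per molecule, normalized to *all* N_mol."""
        return 2.0 * self.n_short_bonds_in_sh / self.n_mol

    @property
    def mean_bonds_per_sh_molecule(self) -> float:
        """Variant normalized to SH member count only."""
        if self.n_sh_molecules == 0:
            return 0.0
        return 2.0 * self.n_short_bonds_in_sh / self.n_sh_molecules

    def degree_fractions(self, max_degree: int = 4) -> np.ndarray:
        """Fractions of SH molecules with 1..max_degree (last bucket
        inclusive of higher degrees) short H-bonds; sums to 1 when SHs
        exist."""
        frac = np.zeros(max_degree + 1)
        for k, c in enumerate(self.degree_counts):
            frac[min(k, max_degree)] += c
        if self.n_sh_molecules:
            frac = frac / self.n_sh_molecules
        return frac


def short_bond_degree_stats(
    classified: ClassifiedNetwork, decomp: SHDecomposition
) -> ShortBondDegreeStats:
    """Per-molecule short-bond degrees, counted only inside SHs."""
    members = decomp.member_index_set()
    edges = decomp.short_edges
    if len(edges):
        keep = np.array([i in members and j in members for i, j in edges], dtype=bool)
        edges = edges[keep]
    deg = np.zeros(decomp.n_mol, dtype=np.int64)
    if len(edges):
        np.add.at(deg, edges[:, 0], 1)
        np.add.at(deg, edges[:, 1], 1)
    member_idx = np.array(sorted(members), dtype=np.int64)
    member_deg = deg[member_idx] if len(member_idx) else np.zeros(0, dtype=np.int64)
    return ShortBondDegreeStats(
        frame_time=decomp.frame_time,
        n_mol=decomp.n_mol,
        n_sh_molecules=len(member_idx),
        n_short_bonds_in_sh=len(edges),
        degree_counts=np.bincount(member_deg, minlength=1)
        if len(member_deg)
        else np.zeros(1, dtype=np.int64),
    )
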