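"""Deterministic generators for test configurations.

The analysis pipeline consumes MD trajectories; these generators stand
in for them so every stage is testable without running a simulation:

* ``generate_ice_ih``     -- hexagonal ice Ih with seeded proton
  disorder satisfying the Bernal-Fowler ice rules (each oxygen binds
  two hydrogens covalently; each nearest-neighbor O...O link carries
  exactly one hydrogen).
* ``generate_dimer``      -- two rigid molecules at a prescribed O...O
  distance and H-O...O angle, for pair-energy scans.
* ``generate_liquid_like``-- perturbed, density-rescaled ice lattice
  with a tunable realized fraction of short H-bonds.
* ``generate_planted_components`` -- frames with short-H-bond chains of
  exactly known sizes (ground truth for heterogeneity detection).

All generators are pure functions of their arguments: the same seed
yields bit-identical frames.  They make no claim to reproduce real
TIP4P/2005 thermodynamics; they provide controllable structure.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core import Frame, ModelGeometry, SimulationBox, TIP4P2005_GEOMETRY

__all__ = [
    "generate_ice_ih",
    "generate_dimer",
    "generate_liquid_like",
    "generate_planted_components",
    "ice_oxygen_lattice",
    "audit_ice_rules",
    "DEFAULT_A",
    "DEFAULT_C",
]

# Fixture lattice constants, chosen so the nearest O...O distance is
# ~2.76 A (sqrt(3/8)*a with a near-ideal c/a ratio).
DEFAULT_A = 4.5181
DEFAULT_C = 7.3560

WATER_MOLAR_MASS = 18.01528  # g/mol
AVOGADRO = 6.02214076e23


def _orthorhombic_ice_cell(a: float, c: float) -> tuple[np.ndarray, np.ndarray]:
    """8-oxygen orthorhombic cell (a, a*sqrt(3), c) of the ice Ih
    oxygen sublattice (lonsdaleite positions)."""
    # hexagonal 4-atom basis (fractional, hexagonal axes), z = 1/16
    z = 1.0 / 16.0
    hex_frac = np.array(
        [
            [1 / 3, 2 / 3, z],
            [2 / 3, 1 / 3, 0.5 + z],
            [2 / 3, 1 / 3, 1.0 - z],
            [1 / 3, 2 / 3, 0.5 - z],
        ]
    )
    b = a * math.sqrt(3.0)
    lengths = np.array([a, b, c])
    # hexagonal -> cartesian, then duplicate shifted by (a/2, b/2, 0)
    cart = np.empty_like(hex_frac)
    cart[:, 0] = (hex_frac[:, 0] - 0.5 * hex_frac[:, 1]) * a
    cart[:, 1] = hex_frac[:, 1] * (math.sqrt(3.0) / 2.0) * a
    cart[:, 2] = hex_frac[:, 2] * c
    cell = np.vstack([cart, cart + np.array([a / 2.0, b / 2.0, 0.0])])
    return np.mod(cell, lengths), lengths


def ice_oxygen_lattice(
    cells: tuple[int, int, int], a: float = DEFAULT_A, c: float = DEFAULT_C
) -> tuple[np.ndarray, SimulationBox]:
    """Oxygen positions of an nx x ny x nz ice Ih supercell."""
    nx, ny, nz = cells
    if min(nx, ny, nz) < 1:
        raise ValueError("need at least one cell in every direction")
    base, lengths = _orthorhombic_ice_cell(a, c)
    shifts = np.array(
        [[i, j, k] for i in range(nx) for j in range(ny) for k in range(nz)], dtype=float
    )
    pos = (base[None, :, :] + (shifts * lengths)[:, None, :]).reshape(-1, 3)
    box = SimulationBox(lengths * np.array([nx, ny, nz], dtype=float))
    return pos, box


def _neighbor_graph(pos: np.ndarray, box: SimulationBox, cutoff: float = 3.0):
    """Nearest-neighbor O-O adjacency with minimum-image unit vectors."""
    from scipy.spatial import cKDTree

    L = box.lengths
    wrapped = np.mod(pos, L)
    tree = cKDTree(wrapped, boxsize=L)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    d -= L * np.floor(d / L + 0.5)
    return pairs, d / np.linalg.norm(d, axis=1, keepdims=True)


def _euler_orientation(n: int, pairs: np.ndarray) -> dict[int, set[int]]:
    """Initial ice-rule orientation: direct each edge along an Eulerian
    circuit of the 4-regular O-O graph, giving out-degree 2 everywhere."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(map(tuple, pairs))
    if not nx.is_connected(G):
        raise ValueError("ice oxygen lattice graph is not connected")
    out: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, v in nx.eulerian_circuit(G):
        out[u].add(v)
    return out


def _loop_reversals(out: dict[int, set[int]], rng: np.random.Generator, n_flips: int) -> None:
    """Seeded proton-disorder sampling: reverse random directed loops.

    Reversing a directed cycle preserves every out-degree, so the ice
    rules survive each flip.
    """
    nodes = sorted(out)
    for _ in range(n_flips):
        start = int(rng.choice(nodes))
        path = [start]
        where = {start: 0}
        cur = start
        while True:
            nbrs = sorted(out[cur])
            cur = int(nbrs[rng.integers(len(nbrs))])
            if cur in where:
                cycle = path[where[cur] :] + [cur]
                for u, v in zip(cycle[:-1], cycle[1:]):
                    out[u].remove(v)
                    out[v].add(u)
                break
            where[cur] = len(path)
            path.append(cur)


def _place_hydrogens(
    pos: np.ndarray,
    box: SimulationBox,
    out: dict[int, set[int]],
    unit: dict[tuple[int, int], np.ndarray],
    geom: ModelGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid H placement: molecular bisector along the bisector of the
    two donated O...O directions, hydrogens in that plane at theta_HOH.

    Because theta_HOH (104.52 deg) is below the tetrahedral angle, each
    O-H tilts ~2.5 deg off its donated O...O axis -- well inside the
    [0, 10] deg band of ice.
    """
    n = len(pos)
    H1 = np.empty((n, 3))
    H2 = np.empty((n, 3))
    half = math.radians(geom.theta_HOH / 2.0)
    for i in range(n):
        d1, d2 = (unit[(i, j)] for j in sorted(out[i]))
        bis = d1 + d2
        bis /= np.linalg.norm(bis)
        perp = d1 - d2
        perp /= np.linalg.norm(perp)
        H1[i] = pos[i] + geom.r_OH * (math.cos(half) * bis + math.sin(half) * perp)
        H2[i] = pos[i] + geom.r_OH * (math.cos(half) * bis - math.sin(half) * perp)
    return H1, H2


def generate_ice_ih(
    cells: tuple[int, int, int] = (2, 2, 2),
    seed: int = 0,
    a: float = DEFAULT_A,
    c: float = DEFAULT_C,
    geom: ModelGeometry = TIP4P2005_GEOMETRY,
    flips_per_molecule: int = 10,
) -> Frame:
    """Hexagonal ice Ih frame with seeded Bernal-Fowler proton disorder."""
    pos, box = ice_oxygen_lattice(cells, a, c)
    if box.min_length <= 2 * 3.2:
        raise ValueError(
            f"supercell too small for minimum image at the 3.2 A cutoff: "
            f"lengths {box.lengths}"
        )
    pairs, units = _neighbor_graph(pos, box)
    deg = np.bincount(pairs.ravel(), minlength=len(pos))
    if not np.all(deg == 4):
        raise RuntimeError("ice lattice construction failed: non-4-coordinated oxygen")
    unit = {}
    for (i, j), u in zip(map(tuple, pairs), units):
        unit[(i, j)] = u
        unit[(j, i)] = -u
    out = _euler_orientation(len(pos), pairs)
    rng = np.random.default_rng(seed)
    _loop_reversals(out, rng, flips_per_molecule * len(pos))
    H1, H2 = _place_hydrogens(pos, box, out, unit, geom)
    return Frame(0.0, box, np.arange(1, len(pos) + 1), pos, H1, H2)


def audit_ice_rules(frame: Frame, cutoff: float = 3.0, axis_tol: float = 15.0) -> bool:
    """Geometric ice-rule audit of a generated ice frame.

    Each molecule carries two covalent hydrogens by construction; the
    audit checks that every nearest-neighbor O...O link hosts exactly
    one hydrogen (one of the two oxygens points an O-H along the link,
    within ``axis_tol`` degrees).
    """
    from .hbonds import _candidate_angle_matrix
    from .network import build_bond_network

    net = build_bond_network(frame, r_cut=cutoff)
    ang = _candidate_angle_matrix(frame, net)
    donated = (ang < axis_tol).sum(axis=1)
    return bool(np.all(donated == 1))


def _canonical_molecule(geom: ModelGeometry) -> tuple[np.ndarray, np.ndarray]:
    """H offsets for a molecule with H1 along +x and H2 in the xz-plane."""
    th = math.radians(geom.theta_HOH)
    h1 = geom.r_OH * np.array([1.0, 0.0, 0.0])
    h2 = geom.r_OH * np.array([math.cos(th), 0.0, -math.sin(th)])
    return h1, h2


def _rot_y(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    ca, sa = math.cos(a), math.sin(a)
    return np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])


def generate_dimer(
    R: float,
    angle: float,
    acceptor_tilt: float = 52.0,
    geom: ModelGeometry = TIP4P2005_GEOMETRY,
    box_length: float | None = None,
) -> Frame:
    """Two rigid molecules: donor at the origin with one O-H tilted by
    ``angle`` degrees from the O...O axis, acceptor at distance ``R``.

    The acceptor sits in the conventional near-minimum arrangement:
    H-O-H plane perpendicular to the donor (xz) plane, bisector in the
    xz-plane tilted ``acceptor_tilt`` degrees from the O...O axis with
    the hydrogens pointing away from the donor.
    """
    if R <= 0:
        raise ValueError("O...O distance must be positive")
    L = box_length if box_length is not None else max(10.0 * R, 40.0)
    box = SimulationBox(np.array([L, L, L]))
    # donor oxygen at the origin keeps the requested O...O distance exact
    # in floating point; minimum image handles the unwrapped coordinates
    center = np.zeros(3)

    h1, h2 = _canonical_molecule(geom)
    Rm = _rot_y(angle)  # tilts H1 from +x toward +z
    dO = center
    dH1 = center + Rm @ h1
    dH2 = center + Rm @ h2

    aO = center + np.array([R, 0.0, 0.0])
    tau = math.radians(acceptor_tilt)
    bis = np.array([math.cos(tau), 0.0, math.sin(tau)])  # away from donor
    perp = np.array([0.0, 1.0, 0.0])
    half = math.radians(geom.theta_HOH / 2.0)
    aH1 = aO + geom.r_OH * (math.cos(half) * bis + math.sin(half) * perp)
    aH2 = aO + geom.r_OH * (math.cos(half) * bis - math.sin(half) * perp)

    return Frame(
        0.0,
        box,
        [1, 2],
        np.array([dO, aO]),
        np.array([dH1, aH1]),
        np.array([dH2, aH2]),
    )


def _random_rotation_matrices(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotations from unit quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=1,
    )


def _short_fraction(frame: Frame) -> float:
    from .hbonds import HBondCriteria, classify_pairs
    from .network import build_bond_network

    net = build_bond_network(frame)
    if net.n_pairs == 0:
        return 0.0
    return classify_pairs(frame, net, HBondCriteria()).n_short / net.n_pairs


def _perturbed_frame(
    base: Frame,
    rng: np.random.Generator,
    noise: float,
    rotate_order: np.ndarray,
    n_rotate: int,
    time: float,
) -> Frame:
    shift = rng.normal(0.0, noise, size=(base.n_mol, 3)) if noise > 0 else 0.0
    O = base.O + shift
    H1 = base.H1 + shift
    H2 = base.H2 + shift
    rot = _random_rotation_matrices(rng, base.n_mol)
    idx = rotate_order[:n_rotate]
    if len(idx):
        for name, arr in (("H1", H1), ("H2", H2)):
            v = arr[idx] - O[idx]
            arr[idx] = O[idx] + np.einsum("nij,nj->ni", rot[idx], v)
    return Frame(time, base.box, base.molecule_ids, O, H1, H2)


def generate_liquid_like(
    n_mol: int = 96,
    density: float = 0.997,
    seed: int = 0,
    noise: float = 0.12,
    target_short_fraction: float | None = None,
    n_frames: int = 1,
    dt: float = 1.0,
    tolerance: float = 0.02,
    max_iter: int = 40,
    rotate_fraction: float = 0.5,
    geom: ModelGeometry = TIP4P2005_GEOMETRY,
) -> tuple[list[Frame], dict]:
    """Liquid-like frames: density-rescaled ice lattice with Gaussian
    positional noise and random rotations of a seeded molecule subset.

    When ``target_short_fraction`` is given, the number of rotated
    molecules is tuned by bisection until the realized fraction of
    network pairs that are short H-bonds is within ``tolerance``
    (absolute) of the target.  Returns the frames and a metadata dict
    with the realized values.

    The requested ``n_mol`` is rounded up to the nearest full ice
    supercell (multiples of 8); the realized count is in the metadata.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if target_short_fraction is not None and not (0.0 <= target_short_fraction <= 1.0):
        raise ValueError("target_short_fraction must lie in [0, 1]")
    # smallest near-isotropic supercell with >= n_mol molecules and a
    # box large enough for the 3.2 A cutoff after density rescaling
    nx = ny = nz = 2
    while 8 * nx * ny * nz < n_mol:
        dims = [nx, ny, nz]
        dims[int(np.argmin([nx * DEFAULT_A, ny * DEFAULT_A * math.sqrt(3), nz * DEFAULT_C]))] += 1
        nx, ny, nz = dims
    base = generate_ice_ih((nx, ny, nz), seed=seed, geom=geom)

    # isotropic rescale to the requested mass density
    volume = float(np.prod(base.box.lengths))  # A^3
    target_volume = (base.n_mol * WATER_MOLAR_MASS / (AVOGADRO * density)) * 1e24
    s = (target_volume / volume) ** (1.0 / 3.0)
    box = SimulationBox(base.box.lengths * s)
    box.check_cutoff(3.2)
    O = base.O * s
    # molecules translate rigidly with their oxygen; intramolecular geometry unscaled
    base = Frame(0.0, box, base.molecule_ids, O, O + (base.H1 - base.O), O + (base.H2 - base.O))

    rng = np.random.default_rng(seed)
    rotate_order = rng.permutation(base.n_mol)

    def make(n_rotate: int, time: float, frame_rng: np.random.Generator) -> Frame:
        return _perturbed_frame(base, frame_rng, noise, rotate_order, n_rotate, time)

    def tune(frame_seed: int) -> int:
        # realized fraction decreases with the number of rotated molecules,
        # but only statistically -- use a coarse grid then a local scan
        def realized(k: int) -> float:
            return _short_fraction(make(k, 0.0, np.random.default_rng(frame_seed)))

        step = max(1, base.n_mol // (max_iter - 8))
        history = [(k, realized(k)) for k in range(0, base.n_mol + 1, step)]
        k0 = min(history, key=lambda kf: abs(kf[1] - target_short_fraction))[0]
        for k in range(max(0, k0 - step), min(base.n_mol, k0 + step) + 1):
            if not any(k == h[0] for h in history):
                history.append((k, realized(k)))
        best_k, best_f = min(history, key=lambda kf: abs(kf[1] - target_short_fraction))
        if abs(best_f - target_short_fraction) > tolerance:
            raise RuntimeError(
                f"could not reach short-bond fraction {target_short_fraction} "
                f"within +/-{tolerance} (best {best_f:.3f} at {best_k} rotations); "
                f"search history (n_rotated, realized): {sorted(history)}"
            )
        return best_k

    frames = []
    realized_fractions = []
    n_rotated = []
    for k in range(n_frames):
        frame_seed = seed + 1 + k
        if target_short_fraction is None:
            n_rotate = int(round(rotate_fraction * base.n_mol))
        else:
            n_rotate = tune(frame_seed)
        fr = make(n_rotate, k * dt, np.random.default_rng(frame_seed))
        frames.append(fr)
        realized_fractions.append(_short_fraction(fr))
        n_rotated.append(int(n_rotate))
    meta = {
        "n_mol": base.n_mol,
        "cells": (nx, ny, nz),
        "density": density,
        "noise": noise,
        "n_rotated": n_rotated,
        "target_short_fraction": target_short_fraction,
        "realized_short_fraction": realized_fractions,
        "seed": seed,
    }
    return frames, meta


def generate_planted_components(
    component_sizes: Sequence[int],
    n_mol: int,
    seed: int = 0,
    chain_spacing: float = 2.70,
    row_spacing: float = 4.0,
    geom: ModelGeometry = TIP4P2005_GEOMETRY,
) -> Frame:
    """Frame containing short-H-bond chains of exactly the given sizes.

    Each chain occupies its own grid row with consecutive oxygens
    ``chain_spacing`` apart (short H-bonds, donor O-H on the O...O
    axis); all other molecules are isolated fillers at ``row_spacing``
    so no further pair passes the short criterion.
    """
    sizes = list(component_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("component sizes must be positive")
    if sum(sizes) > n_mol:
        raise ValueError("sum of component sizes exceeds n_mol")
    n_fill = n_mol - sum(sizes)
    fill_per_row = max(1, int(math.ceil(math.sqrt(n_fill))) if n_fill else 1)
    rows: list[list[float]] = [
        [i * chain_spacing for i in range(s)] for s in sizes
    ]
    for start in range(0, n_fill, fill_per_row):
        count = min(fill_per_row, n_fill - start)
        rows.append([i * row_spacing for i in range(count)])

    max_x = max((r[-1] for r in rows), default=0.0)
    Lx = max(max_x + row_spacing, 2 * 3.2 + 0.5)
    n_rows = len(rows)
    side = max(1, int(math.ceil(math.sqrt(n_rows))))
    Ly = max(side * row_spacing, 2 * 3.2 + 0.5)
    Lz = max(int(math.ceil(n_rows / side)) * row_spacing, 2 * 3.2 + 0.5)
    box = SimulationBox(np.array([Lx, Ly, Lz]))

    h1, h2 = _canonical_molecule(geom)
    O, H1, H2 = [], [], []
    for r, xs in enumerate(rows):
        y = (r % side) * row_spacing + 1.0
        z = (r // side) * row_spacing + 1.0
        for x in xs:
            o = np.array([x + 1.0, y, z])
            O.append(o)
            H1.append(o + h1)  # donates along +x, toward the next chain member
            H2.append(o + h2)
    frame = Frame(0.0, box, np.arange(1, n_mol + 1), np.array(O), np.array(H1), np.array(H2))
    return frame
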