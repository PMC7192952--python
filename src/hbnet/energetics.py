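"""TIP4P/2005 pair interaction energies.

The pair energy of two rigid molecules is the direct (non-Ewald) sum

    U = 4*eps[(sigma/r_OO)^12 - (sigma/r_OO)^6]
        + k_e * sum_{i in {H1,H2,M}(a)} sum_{j in {H1,H2,M}(b)} q_i q_j / r_ij

with one Lennard-Jones term between the oxygens and nine Coulomb terms
between the charged sites (two hydrogens and the M-site of each
molecule).  Site-site distances use the minimum image of the molecule
pair: the partner molecule is shifted as a whole to its nearest
periodic image.  This is a two-body quantity -- the periodic lattice
sum of the simulation Hamiltonian is deliberately not evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    Frame,
    ModelGeometry,
    SimulationBox,
    TIP4P2005_GEOMETRY,
    WaterMolecule,
    minimum_image_displacement,
    reconstruct_m_site,
)
from .hbonds import LABEL_HBOND, LABEL_SHORT, ClassifiedNetwork
from .network import Histogram, histogram_over_frames

__all__ = [
    "TIP4P2005Params",
    "PairEnergyTable",
    "DimerSurface",
    "pair_interaction_energy",
    "pair_energies",
    "dimer_energy_surface",
    "energy_histogram",
    "mean_short_bond_energy",
]

#: Coulomb constant in kcal*A/(mol*e^2)
COULOMB_KCAL = 332.0636


@dataclass(frozen=True)
class TIP4P2005Params:
    """Charges and Lennard-Jones parameters of the TIP4P/2005 model
    (Abascal & Vega 2005): q_H = 0.5564 e on each hydrogen, the
    balancing negative charge on the M-site, LJ on oxygen only."""

    q_H: float = 0.5564
    q_M: float = -1.1128
    sigma_OO: float = 3.1589
    epsilon_OO: float = 0.1852
    k_e: float = COULOMB_KCAL
    geometry: ModelGeometry = field(default_factory=ModelGeometry)

    def __post_init__(self) -> None:
        if abs(self.q_M + 2.0 * self.q_H) > 1e-9:
            raise ValueError("charge neutrality requires q_M = -2 q_H")
        if self.sigma_OO <= 0 or self.epsilon_OO <= 0:
            raise ValueError("LJ parameters must be positive")

    @property
    def charges(self) -> np.ndarray:
        return np.array([self.q_H, self.q_H, self.q_M])


DEFAULT_PARAMS = TIP4P2005Params()

_MIN_SITE_DIST = 1e-6


def _charged_sites(mol: WaterMolecule, geom: ModelGeometry) -> np.ndarray:
    M = mol.M if mol.M is not None else reconstruct_m_site(mol, geom)
    return np.array([mol.H1, mol.H2, M])


def pair_interaction_energy(
    a: WaterMolecule,
    b: WaterMolecule,
    box: SimulationBox,
    params: TIP4P2005Params = DEFAULT_PARAMS,
) -> float:
    """Direct Coulomb + Lennard-Jones energy of one molecule pair, kcal/mol."""
    roff = minimum_image_displacement(a.O, b.O, box)
    shift = roff - (b.O - a.O)
    r_OO = float(np.linalg.norm(roff))
    if r_OO < _MIN_SITE_DIST:
        raise ValueError("overlapping oxygens: pair energy undefined")
    sa = _charged_sites(a, params.geometry)
    sb = _charged_sites(b, params.geometry) + shift
    d = np.linalg.norm(sa[:, None, :] - sb[None, :, :], axis=2)
    if np.any(d < _MIN_SITE_DIST):
        raise ValueError("overlapping charged sites: pair energy undefined")
    q = params.charges
    u_coul = params.k_e * float((q[:, None] * q[None, :] / d).sum())
    x6 = (params.sigma_OO / r_OO) ** 6
    u_lj = 4.0 * params.epsilon_OO * (x6 * x6 - x6)
    return u_lj + u_coul


def pair_energies(
    frame: Frame,
    pairs: np.ndarray,
    params: TIP4P2005Params = DEFAULT_PARAMS,
) -> np.ndarray:
    """Vectorised pair energies for (P, 2) index pairs of one frame.

    The frame must carry M-sites (``Frame.with_m_sites``).
    """
    if frame.M is None:
        frame = frame.with_m_sites(params.geometry)
    if len(pairs) == 0:
        return np.zeros(0)
    i, j = pairs[:, 0], pairs[:, 1]
    roff = minimum_image_displacement(frame.O[i], frame.O[j], frame.box)
    shift = roff - (frame.O[j] - frame.O[i])  # move j to its nearest image
    r_OO = np.linalg.norm(roff, axis=1)
    if np.any(r_OO < _MIN_SITE_DIST):
        raise ValueError("overlapping oxygens in pair list")
    sa = np.stack([frame.H1[i], frame.H2[i], frame.M[i]], axis=1)  # (P,3,3)
    sb = np.stack([frame.H1[j], frame.H2[j], frame.M[j]], axis=1) + shift[:, None, :]
    d = np.linalg.norm(sa[:, :, None, :] - sb[:, None, :, :], axis=3)  # (P,3,3)
    if np.any(d < _MIN_SITE_DIST):
        raise ValueError("overlapping charged sites in pair list")
    q = params.charges
    u_coul = params.k_e * (q[None, :, None] * q[None, None, :] / d).sum(axis=(1, 2))
    x6 = (params.sigma_OO / r_OO) ** 6
    u_lj = 4.0 * params.epsilon_OO * (x6 * x6 - x6)
    return u_lj + u_coul


@dataclass
class PairEnergyTable:
    """Per-network-pair energies of one frame, with H-bond labels."""

    frame_time: float
    n_mol: int
    pairs: np.ndarray  # (P, 2)
    U: np.ndarray  # (P,) kcal/mol
    labels: np.ndarray  # (P,) from hbond classification

    @classmethod
    def from_classified(
        cls,
        frame: Frame,
        classified: ClassifiedNetwork,
        params: TIP4P2005Params = DEFAULT_PARAMS,
    ) -> "PairEnergyTable":
        U = pair_energies(frame, classified.net.pairs, params)
        return cls(
            frame_time=classified.net.frame_time,
            n_mol=classified.net.n_mol,
            pairs=classified.net.pairs,
            U=U,
            labels=classified.labels,
        )


_SPLIT_MASKS = {
    "all": lambda labels: np.ones(len(labels), dtype=bool),
    "hbonded": lambda labels: labels >= LABEL_HBOND,
    "nonbonded": lambda labels: labels < LABEL_HBOND,
    "short_hbonded": lambda labels: labels == LABEL_SHORT,
}


def energy_histogram(
    tables: Sequence[PairEnergyTable],
    bin_width: float = 0.1,
    split: str = "all",
    normalization: str = "raw",
    lo: float = -10.0,
    hi: float = 10.0,
) -> Histogram:
    """Time-averaged pair-energy distribution (0.1 kcal/mol step).

    ``split`` selects all / hbonded / nonbonded / short_hbonded pairs.
    ``normalization``: 'raw' (mean per-frame counts), 'per_pairs',
    'per_hbonds' or 'per_short' divide by the mean per-frame number of
    network pairs, H-bonds or short H-bonds respectively.
    """
    if len(tables) == 0:
        raise ValueError("need at least one pair-energy table")
    try:
        mask_fn = _SPLIT_MASKS[split]
    except KeyError:
        raise ValueError(f"unknown split {split!r}; choose from {sorted(_SPLIT_MASKS)}")
    samples = [t.U[mask_fn(t.labels)] for t in tables]
    hist = histogram_over_frames(samples, bin_width, lo, hi, "raw")
    divisors = {
        "raw": 1.0,
        "per_pairs": np.mean([len(t.U) for t in tables]),
        "per_hbonds": np.mean([int((t.labels >= LABEL_HBOND).sum()) for t in tables]),
        "per_short": np.mean([int((t.labels == LABEL_SHORT).sum()) for t in tables]),
    }
    if normalization not in divisors:
        raise ValueError(f"unknown normalization {normalization!r}")
    div = divisors[normalization]
    if div == 0:
        raise ValueError(f"normalization {normalization!r} divisor is zero")
    return Histogram(hist.edges, hist.values / div, normalization)


def mean_short_bond_energy(
    tables: Sequence[PairEnergyTable],
    decompositions: Sequence["object"] | None = None,
) -> np.ndarray:
    """Per-frame mean energy of short H-bonds inside heterogeneities.

    ``decompositions`` are the matching per-frame ``SHDecomposition``
    objects; when given, only short bonds whose two molecules both
    belong to a detected heterogeneity (component of size >= size_min)
    contribute, mirroring the exclusion of 2-4 molecule groups.  Frames
    with no qualifying bond yield NaN (missing, not zero).
    """
    out = np.full(len(tables), np.nan)
    for k, t in enumerate(tables):
        mask = t.labels == LABEL_SHORT
        if decompositions is not None:
            members = decompositions[k].member_index_set()
            in_sh = np.array(
                [i in members and j in members for i, j in t.pairs], dtype=bool
            ) if len(t.pairs) else np.zeros(0, dtype=bool)
            mask = mask & in_sh
        if mask.any():
            out[k] = float(t.U[mask].mean())
    return out


@dataclass
class DimerSurface:
    """U(R, angle) grid of the two-molecule energy plus per-angle minima."""

    R_grid: np.ndarray
    angle_grid: np.ndarray
    U: np.ndarray  # (len(R_grid), len(angle_grid))
    min_R: np.ndarray  # per-angle location of the refined minimum
    min_U: np.ndarray  # per-angle refined minimum depth
    acceptor_tilt: float


def _dimer_energy(R: float, angle: float, params: TIP4P2005Params, acceptor_tilt: float) -> float:
    from .fixtures import generate_dimer

    frame = generate_dimer(R, angle, acceptor_tilt=acceptor_tilt, geom=params.geometry)
    return pair_interaction_energy(frame.molecule(0), frame.molecule(1), frame.box, params)


def dimer_energy_surface(
    R_grid: Sequence[float],
    angle_grid: Sequence[float],
    params: TIP4P2005Params = DEFAULT_PARAMS,
    acceptor_tilt: float = 52.0,
    refine_tol: float = 1e-4,
) -> DimerSurface:
    """Two-molecule energy surface over O...O distance and H-O...O angle.

    The donor tilts one O-H off the O...O axis by the scan angle; the
    acceptor keeps the canonical near-minimum orientation (bisector in
    the dimer plane at ``acceptor_tilt`` degrees, hydrogens away from
    the donor).  Per-angle minima are refined by bounded scalar
    minimisation after grid bracketing.
    """
    from scipy.optimize import minimize_scalar

    R_grid = np.asarray(R_grid, dtype=float)
    angle_grid = np.asarray(angle_grid, dtype=float)
    if len(R_grid) == 0 or len(angle_grid) == 0:
        raise ValueError("grids must be nonempty")
    U = np.empty((len(R_grid), len(angle_grid)))
    for aidx, ang in enumerate(angle_grid):
        for ridx, R in enumerate(R_grid):
            U[ridx, aidx] = _dimer_energy(float(R), float(ang), params, acceptor_tilt)
    min_R = np.empty(len(angle_grid))
    min_U = np.empty(len(angle_grid))
    for aidx, ang in enumerate(angle_grid):
        k = int(np.argmin(U[:, aidx]))
        lo = R_grid[max(0, k - 1)]
        hi = R_grid[min(len(R_grid) - 1, k + 1)]
        if lo == hi:
            min_R[aidx], min_U[aidx] = R_grid[k], U[k, aidx]
            continue
        res = minimize_scalar(
            lambda R: _dimer_energy(float(R), float(ang), params, acceptor_tilt),
            bounds=(float(lo), float(hi)),
            method="bounded",
            options={"xatol": refine_tol},
        )
        min_R[aidx] = float(res.x)
        min_U[aidx] = float(res.fun)
    return DimerSurface(R_grid, angle_grid, U, min_R, min_U, acceptor_tilt)
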