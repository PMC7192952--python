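"""Domain types and periodic-boundary geometry for rigid-water analysis.

Coordinates are in Angstrom, times in femtoseconds, angles in degrees
throughout the package.  All inter-molecular geometry goes through the
minimum-image convention for orthorhombic boxes; wrapped and unwrapped
input coordinates are therefore treated identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SimulationBox",
    "ModelGeometry",
    "WaterMolecule",
    "Frame",
    "RigidityReport",
    "TIP4P2005_GEOMETRY",
    "minimum_image_displacement",
    "reconstruct_m_site",
    "reconstruct_m_sites",
    "validate_rigidity",
]


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic cell.

    Parameters
    ----------
    lengths : array-like of 3 floats
        Edge lengths in Angstrom; all must be positive.
    origin : array-like of 3 floats, optional
        Lower corner of the cell (only relevant for wrapping on output).
    """

    lengths: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        origin = np.asarray(self.origin, dtype=float)
        if lengths.shape != (3,) or origin.shape != (3,):
            raise ValueError("box lengths and origin must be 3-vectors")
        if not np.all(lengths > 0):
            raise ValueError(f"box lengths must be positive, got {lengths}")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "origin", origin)

    @property
    def min_length(self) -> float:
        return float(self.lengths.min())

    def check_cutoff(self, cutoff: float) -> None:
        """Raise if *cutoff* invalidates the minimum-image convention."""
        if cutoff >= self.min_length / 2.0:
            raise ValueError(
                f"cutoff {cutoff} A >= half the smallest box length "
                f"({self.min_length / 2.0} A): minimum image is invalid"
            )


#: Rigid four-site geometry of the TIP4P/2005 water model
#: (Abascal & Vega, J. Chem. Phys. 123, 234505, 2005).
@dataclass(frozen=True)
class ModelGeometry:
    """Rigid water geometry: O-H length, H-O-H angle, O-M distance.

    The M-site is the massless charge site on the H-O-H bisector,
    displaced from the oxygen toward the hydrogens by ``d_OM``.
    """

    r_OH: float = 0.9572
    theta_HOH: float = 104.52
    d_OM: float = 0.1546

    def __post_init__(self) -> None:
        if not (self.r_OH > 0 and self.theta_HOH > 0 and self.d_OM >= 0):
            raise ValueError("geometry parameters must be positive")


TIP4P2005_GEOMETRY = ModelGeometry()


@dataclass
class WaterMolecule:
    """One rigid water molecule: oxygen, two hydrogens, optional M-site."""

    molecule_id: int
    O: np.ndarray
    H1: np.ndarray
    H2: np.ndarray
    M: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O, dtype=float)
        self.H1 = np.asarray(self.H1, dtype=float)
        self.H2 = np.asarray(self.H2, dtype=float)
        if self.M is not None:
            self.M = np.asarray(self.M, dtype=float)


class Frame:
    """One instantaneous configuration: time, box and molecule sites.

    Stores sites as ``(N, 3)`` arrays for vectorised analysis; the
    ``molecules`` accessor provides a per-molecule object view.
    """

    def __init__(
        self,
        time: float,
        box: SimulationBox,
        molecule_ids: Sequence[int],
        O: np.ndarray,
        H1: np.ndarray,
        H2: np.ndarray,
        M: np.ndarray | None = None,
    ) -> None:
        self.time = float(time)
        self.box = box
        self.molecule_ids = np.asarray(molecule_ids, dtype=np.int64)
        self.O = np.asarray(O, dtype=float)
        self.H1 = np.asarray(H1, dtype=float)
        self.H2 = np.asarray(H2, dtype=float)
        self.M = None if M is None else np.asarray(M, dtype=float)
        n = len(self.molecule_ids)
        for name in ("O", "H1", "H2"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if len(np.unique(self.molecule_ids)) != n:
            raise ValueError("molecule ids must be unique within a frame")

    @property
    def n_mol(self) -> int:
        return len(self.molecule_ids)

    @classmethod
    def from_molecules(
        cls, time: float, box: SimulationBox, molecules: Sequence[WaterMolecule]
    ) -> "Frame":
        ids = [m.molecule_id for m in molecules]
        O = np.array([m.O for m in molecules], dtype=float).reshape(-1, 3)
        H1 = np.array([m.H1 for m in molecules], dtype=float).reshape(-1, 3)
        H2 = np.array([m.H2 for m in molecules], dtype=float).reshape(-1, 3)
        return cls(time, box, ids, O, H1, H2)

    def molecules(self) -> Iterator[WaterMolecule]:
        for i in range(self.n_mol):
            M = None if self.M is None else self.M[i]
            yield WaterMolecule(int(self.molecule_ids[i]), self.O[i], self.H1[i], self.H2[i], M)

    def molecule(self, index: int) -> WaterMolecule:
        M = None if self.M is None else self.M[index]
        return WaterMolecule(
            int(self.molecule_ids[index]), self.O[index], self.H1[index], self.H2[index], M
        )

    def with_m_sites(self, geom: ModelGeometry = TIP4P2005_GEOMETRY) -> "Frame":
        """Return a copy of the frame with M-sites reconstructed.

        If M-sites were already present (e.g. read from file) they are
        validated against the reconstruction and the reconstructed
        values are used, for model consistency.
        """
        M = reconstruct_m_sites(self, geom)
        if self.M is not None:
            dev = np.linalg.norm(self.M - M, axis=1).max()
            if dev > 1e-3:
                warnings.warn(
                    f"input M-sites deviate from reconstruction by up to {dev:.2e} A; "
                    "using reconstructed positions",
                    stacklevel=2,
                )
        out = Frame(self.time, self.box, self.molecule_ids, self.O, self.H1, self.H2, M)
        return out


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: SimulationBox
) -> np.ndarray:
    """Shortest periodic image of ``b - a`` in an orthorhombic box.

    Accepts single positions or ``(N, 3)`` arrays (broadcast).  Each
    component of the result lies in ``[-L_i/2, L_i/2)``.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L = box.lengths
    return d - L * np.floor(d / L + 0.5)


def reconstruct_m_site(mol: WaterMolecule, geom: ModelGeometry = TIP4P2005_GEOMETRY) -> np.ndarray:
    """Place the M-site on the H1-O-H2 bisector at ``d_OM`` from the oxygen."""
    b1 = mol.H1 - mol.O
    b2 = mol.H2 - mol.O
    bis = b1 / np.linalg.norm(b1) + b2 / np.linalg.norm(b2)
    nb = np.linalg.norm(bis)
    if not np.isfinite(nb) or nb < 1e-8:
        raise ValueError(
            f"degenerate geometry for molecule {mol.molecule_id}: "
            "cannot construct H-O-H bisector"
        )
    return mol.O + geom.d_OM * bis / nb


def reconstruct_m_sites(frame: Frame, geom: ModelGeometry = TIP4P2005_GEOMETRY) -> np.ndarray:
    """Vectorised M-site reconstruction for every molecule of a frame.

    Hydrogen positions may sit in a different periodic image than their
    oxygen (wrapped input); intramolecular vectors are taken through
    minimum image.
    """
    b1 = minimum_image_displacement(frame.O, frame.H1, frame.box)
    b2 = minimum_image_displacement(frame.O, frame.H2, frame.box)
    n1 = np.linalg.norm(b1, axis=1, keepdims=True)
    n2 = np.linalg.norm(b2, axis=1, keepdims=True)
    if np.any(n1 < 1e-8) or np.any(n2 < 1e-8):
        bad = frame.molecule_ids[(n1[:, 0] < 1e-8) | (n2[:, 0] < 1e-8)]
        raise ValueError(f"degenerate O-H geometry for molecule ids {bad.tolist()}")
    bis = b1 / n1 + b2 / n2
    nb = np.linalg.norm(bis, axis=1, keepdims=True)
    if np.any(nb < 1e-8):
        bad = frame.molecule_ids[nb[:, 0] < 1e-8]
        raise ValueError(f"collinear H-O-H geometry for molecule ids {bad.tolist()}")
    return frame.O + geom.d_OM * bis / nb


@dataclass
class RigidityReport:
    """Molecules whose geometry deviates from the rigid model."""

    violations: list[tuple[int, str, float]]  # (molecule_id, quantity, deviation)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_rigidity(
    frame: Frame,
    geom: ModelGeometry = TIP4P2005_GEOMETRY,
    tol_length: float = 1e-3,
    tol_angle: float = 0.1,
    warn: bool = True,
) -> RigidityReport:
    """Check O-H lengths and the H-O-H angle against the rigid geometry.

    Violations warn by default rather than abort: trajectory dumps
    truncate coordinates, so small deviations are expected.
    """
    b1 = minimum_image_displacement(frame.O, frame.H1, frame.box)
    b2 = minimum_image_displacement(frame.O, frame.H2, frame.box)
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    cosang = np.einsum("ij,ij->i", b1, b2) / np.clip(n1 * n2, 1e-300, None)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    violations: list[tuple[int, str, float]] = []
    for i in range(frame.n_mol):
        mid = int(frame.molecule_ids[i])
        d1 = abs(n1[i] - geom.r_OH)
        d2 = abs(n2[i] - geom.r_OH)
        da = abs(ang[i] - geom.theta_HOH)
        if d1 > tol_length:
            violations.append((mid, "r_OH1", float(d1)))
        if d2 > tol_length:
            violations.append((mid, "r_OH2", float(d2)))
        if da > tol_angle:
            violations.append((mid, "theta_HOH", float(da)))
    report = RigidityReport(violations)
    if warn and violations:
        warnings.warn(
            f"{len(violations)} rigidity violations in frame t={frame.time} fs "
            f"(first: molecule {violations[0][0]}, {violations[0][1]} "
            f"off by {violations[0][2]:.2e})",
            stacklevel=2,
        )
    return report
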