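"""Trajectory readers and result writers.

LAMMPS text dumps are read through MDAnalysis; extended-XYZ files are
read and written by a minimal built-in parser (orthorhombic lattices
only).  Molecules are assembled by grouping one oxygen with its two
covalent hydrogens -- by molecule id when the file carries one, else
by minimum-image distance (< 1.2 A).

All result files are plain text (TSV / JSON / PDB) with '#' metadata
headers, written deterministically: identical inputs and configuration
produce byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .core import Frame, SimulationBox, minimum_image_displacement
from .network import Histogram

__all__ = [
    "read_lammps_dump",
    "write_lammps_dump",
    "read_extxyz",
    "write_extxyz",
    "write_histogram_tsv",
    "write_series_tsv",
    "write_json_summary",
    "write_sh_pdb",
    "write_edge_list_tsv",
    "assemble_molecules",
]

OH_COVALENT_CUTOFF = 1.2  # A


def assemble_molecules(
    box: SimulationBox,
    elements: Sequence[str],
    positions: np.ndarray,
    mol_ids: Sequence[int] | None,
    time: float,
    context: str = "",
) -> Frame:
    """Group O and H atoms into water molecules.

    Prefers explicit molecule ids; falls back to assigning each H to
    its nearest oxygen within the covalent cutoff (logged via warning).
    """
    elements = [e.upper() for e in elements]
    n_atoms = len(elements)
    if n_atoms % 3 != 0:
        raise ValueError(f"{context}: {n_atoms} atoms do not divide into waters")
    o_idx = [i for i, e in enumerate(elements) if e == "O"]
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    if len(o_idx) * 2 != len(h_idx) or len(o_idx) * 3 != n_atoms:
        raise ValueError(
            f"{context}: element counts O={len(o_idx)}, H={len(h_idx)} "
            "are not 1 oxygen : 2 hydrogens"
        )
    positions = np.asarray(positions, dtype=float)

    if mol_ids is not None:
        mol_ids = np.asarray(mol_ids)
        groups: dict[int, dict[str, list[int]]] = {}
        for i, (e, m) in enumerate(zip(elements, mol_ids)):
            groups.setdefault(int(m), {"O": [], "H": []})[e].append(i)
        ids, O, H1, H2 = [], [], [], []
        for m in sorted(groups):
            g = groups[m]
            if len(g["O"]) != 1 or len(g["H"]) != 2:
                raise ValueError(
                    f"{context}: molecule id {m} has {len(g['O'])} O and "
                    f"{len(g['H'])} H atoms"
                )
            ids.append(m)
            O.append(positions[g["O"][0]])
            H1.append(positions[g["H"][0]])
            H2.append(positions[g["H"][1]])
        return Frame(time, box, ids, np.array(O), np.array(H1), np.array(H2))

    # distance-based fallback
    from scipy.spatial import cKDTree

    o_pos = positions[o_idx]
    h_pos = positions[h_idx]
    L = box.lengths
    tree = cKDTree(np.mod(o_pos, L), boxsize=L)
    d, nearest = tree.query(np.mod(h_pos, L), k=1)
    if np.any(d > OH_COVALENT_CUTOFF):
        bad = int(np.argmax(d))
        raise ValueError(
            f"{context}: hydrogen atom index {h_idx[bad]} is {d[bad]:.2f} A "
            "from the nearest oxygen: ambiguous assignment"
        )
    buckets: dict[int, list[int]] = {}
    for h, o in zip(range(len(h_idx)), nearest):
        buckets.setdefault(int(o), []).append(h)
    if any(len(v) != 2 for v in buckets.values()) or len(buckets) != len(o_idx):
        raise ValueError(f"{context}: hydrogen-to-oxygen assignment is not 2 per O")
    warnings.warn(
        f"{context}: no molecule ids; assembled {len(o_idx)} molecules by distance",
        stacklevel=2,
    )
    ids, O, H1, H2 = [], [], [], []
    for k, o in enumerate(sorted(buckets)):
        hs = buckets[o]
        ids.append(k + 1)
        O.append(o_pos[o])
        H1.append(h_pos[hs[0]])
        H2.append(h_pos[hs[1]])
    return Frame(time, box, ids, np.array(O), np.array(H1), np.array(H2))


def _box_from_dimensions(dim: np.ndarray, context: str) -> SimulationBox:
    if dim is None or not np.all(np.isfinite(dim[:3])) or np.any(dim[:3] <= 0):
        raise ValueError(f"{context}: missing or invalid box bounds")
    if not np.allclose(dim[3:], 90.0, atol=1e-6):
        raise ValueError(
            f"{context}: triclinic cell (angles {dim[3:]}) is not supported; "
            "only orthorhombic boxes are handled"
        )
    return SimulationBox(np.asarray(dim[:3], dtype=float))


def read_lammps_dump(
    path: str | Path,
    type_map: Mapping[str, str] | None = None,
    dt_fs: float = 1.0,
) -> Iterator[Frame]:
    """Stream frames from a LAMMPS text dump.

    ``type_map`` maps atom-type strings to elements, e.g.
    ``{"1": "O", "2": "H"}``; without it, the type occurring once per
    three atoms is taken as oxygen.  Times are ``step * dt_fs``.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guessing chatter
        u = mda.Universe(str(path), format="LAMMPSDUMP")
    types = [str(t) for t in u.atoms.types]
    if type_map is None:
        uniq, counts = np.unique(types, return_counts=True)
        if len(uniq) != 2 or sorted(counts) != [len(types) // 3, 2 * len(types) // 3]:
            raise ValueError(
                f"{path}: cannot infer O/H from types {dict(zip(uniq, counts))}; "
                "pass type_map"
            )
        o_type = uniq[np.argmin(counts)]
        type_map = {str(t): ("O" if t == o_type else "H") for t in uniq}
    elements = [type_map[t] for t in types]
    resids = u.atoms.resids
    have_mol = len(np.unique(resids)) > 1 or len(u.atoms) == 3
    for k, ts in enumerate(u.trajectory):
        box = _box_from_dimensions(ts.dimensions, f"{path} frame {k}")
        step = ts.data.get("step", k)
        mol = resids if have_mol else None
        yield assemble_molecules(
            box, elements, ts.positions.astype(float), mol, step * dt_fs, f"{path} frame {k}"
        )


def write_lammps_dump(frames: Iterable[Frame], path: str | Path, dt_fs: float = 1.0) -> None:
    """Write frames as a LAMMPS text dump (id mol type x y z; type 1=O, 2=H)."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            L = frame.box.lengths
            o = frame.box.origin
            fh.write("ITEM: TIMESTEP\n%d\n" % round(frame.time / dt_fs))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % (3 * frame.n_mol))
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for i in range(3):
                fh.write(f"{o[i]:.8f} {o[i] + L[i]:.8f}\n")
            fh.write("ITEM: ATOMS id mol type x y z\n")
            aid = 1
            for i in range(frame.n_mol):
                m = int(frame.molecule_ids[i])
                for typ, pos in ((1, frame.O[i]), (2, frame.H1[i]), (2, frame.H2[i])):
                    fh.write(
                        f"{aid} {m} {typ} {pos[0]:.8f} {pos[1]:.8f} {pos[2]:.8f}\n"
                    )
                    aid += 1


def write_extxyz(frames: Iterable[Frame], path: str | Path) -> None:
    """Write frames in extended-XYZ with Lattice and per-atom mol ids."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            L = frame.box.lengths
            fh.write(f"{3 * frame.n_mol}\n")
            lattice = f"{L[0]:.8f} 0.0 0.0 0.0 {L[1]:.8f} 0.0 0.0 0.0 {L[2]:.8f}"
            fh.write(
                f'Lattice="{lattice}" '
                f"Properties=species:S:1:pos:R:3:mol:I:1 Time={frame.time:.6f}\n"
            )
            for i in range(frame.n_mol):
                m = int(frame.molecule_ids[i])
                for sp, pos in (("O", frame.O[i]), ("H", frame.H1[i]), ("H", frame.H2[i])):
                    fh.write(
                        f"{sp} {pos[0]:.8f} {pos[1]:.8f} {pos[2]:.8f} {m}\n"
                    )


def _parse_extxyz_comment(line: str, context: str) -> tuple[SimulationBox, float, list[str]]:
    import re

    m = re.search(r'Lattice="([^"]+)"', line)
    if not m:
        raise ValueError(f"{context}: extended-XYZ comment line lacks Lattice")
    cell = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
    off = cell - np.diag(np.diag(cell))
    if np.any(np.abs(off) > 1e-8):
        raise ValueError(f"{context}: non-orthorhombic lattice is not supported")
    box = SimulationBox(np.diag(cell).copy())
    tm = re.search(r"Time=([-\d.eE+]+)", line)
    time = float(tm.group(1)) if tm else 0.0
    pm = re.search(r"Properties=(\S+)", line)
    props = pm.group(1).split(":") if pm else ["species", "S", "1", "pos", "R", "3"]
    fields = [props[i] for i in range(0, len(props), 3)]
    return box, time, fields


def read_extxyz(path: str | Path) -> Iterator[Frame]:
    """Stream frames from an extended-XYZ file (orthorhombic Lattice)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        k = 0
        while True:
            header = fh.readline()
            if not header.strip():
                return
            try:
                n_atoms = int(header)
            except ValueError:
                raise ValueError(f"{path} frame {k}: malformed atom-count line {header!r}")
            box, time, fields = _parse_extxyz_comment(fh.readline(), f"{path} frame {k}")
            has_mol = "mol" in fields
            elements, positions, mols = [], [], []
            for _ in range(n_atoms):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise ValueError(f"{path} frame {k}: truncated atom record")
                elements.append(parts[0])
                positions.append([float(x) for x in parts[1:4]])
                if has_mol:
                    mols.append(int(parts[4]))
            yield assemble_molecules(
                box,
                elements,
                np.array(positions),
                mols if has_mol else None,
                time,
                f"{path} frame {k}",
            )
            k += 1


def _metadata_header(metadata: Mapping[str, object]) -> str:
    lines = [f"# {k} = {v}" for k, v in metadata.items()]
    return "\n".join(lines) + ("\n" if lines else "")


def write_histogram_tsv(
    path: str | Path, hist: Histogram, metadata: Mapping[str, object] | None = None
) -> None:
    with Path(path).open("w") as fh:
        fh.write(_metadata_header(metadata or {}))
        fh.write("bin_left\tbin_right\tvalue\n")
        for lo, hi, v in zip(hist.edges[:-1], hist.edges[1:], hist.values):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{v:.10g}\n")


def write_series_tsv(
    path: str | Path,
    times: np.ndarray,
    columns: Mapping[str, np.ndarray],
    metadata: Mapping[str, object] | None = None,
) -> None:
    with Path(path).open("w") as fh:
        fh.write(_metadata_header(metadata or {}))
        names = list(columns)
        fh.write("t_fs\t" + "\t".join(names) + "\n")
        for i, t in enumerate(times):
            vals = "\t".join(f"{columns[n][i]:.10g}" for n in names)
            fh.write(f"{t:.6g}\t{vals}\n")


def write_json_summary(path: str | Path, summary: Mapping[str, object]) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return None if np.isnan(obj) else float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with Path(path).open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def write_sh_pdb(path: str | Path, frame: Frame, components: Sequence[np.ndarray]) -> None:
    """PDB of SH molecules only, one residue per molecule, unwrapped so
    every molecule is contiguous with its component seed."""
    with Path(path).open("w") as fh:
        L = frame.box.lengths
        fh.write(
            f"CRYST1{L[0]:9.3f}{L[1]:9.3f}{L[2]:9.3f}  90.00  90.00  90.00 P 1\n"
        )
        serial = 1
        for comp_id, comp in enumerate(components, start=1):
            anchor = frame.O[comp[0]]
            for idx in comp:
                disp = minimum_image_displacement(anchor, frame.O[idx], frame.box)
                o = anchor + disp
                shift = o - frame.O[idx]
                for name, pos in (
                    ("O", o),
                    ("H1", frame.H1[idx] + shift),
                    ("H2", frame.H2[idx] + shift),
                ):
                    fh.write(
                        "ATOM  %5d %-4s HOH A%4d    %8.3f%8.3f%8.3f  1.00%6.2f\n"
                        % (
                            serial % 100000,
                            name,
                            int(frame.molecule_ids[idx]) % 10000,
                            pos[0],
                            pos[1],
                            pos[2],
                            float(comp_id % 100),
                        )
                    )
                    serial += 1
        fh.write("END\n")


def write_edge_list_tsv(
    path: str | Path,
    rows: Iterable[tuple[float, int, int, float, float]],
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Edge list (t_fs, mol_i, mol_j, d_OO, U) for short bonds in SHs."""
    with Path(path).open("w") as fh:
        fh.write(_metadata_header(metadata or {}))
        fh.write("t_fs\tmol_i\tmol_j\td_OO\tU_kcal_mol\n")
        for t, i, j, d, u in rows:
            fh.write(f"{t:.6g}\t{i}\t{j}\t{d:.6g}\t{u:.6g}\n")
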