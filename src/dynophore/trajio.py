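"""Topology/trajectory data model, PDB I/O and the selection mini-language.

File parsing is delegated to MDAnalysis (PDB with CONECT, DCD, XTC); the
results are converted into small immutable containers that the rest of the
package operates on. Coordinates are always in Å, times in ps. Residue
numbering is taken verbatim from the input file; frames are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .elements import (
    METALS,
    covalent_radius,
    element_from_atom_name,
    vdw_radius,
)
from .errors import ParseError, SelectionError, ShapeError

#: Residue names treated as standard amino acids (Cα shortcut, protein class).
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL MSE HID HIE HIP ASH GLH LYN CYX".split()
)
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "T3P"})
HYDROXIDE_RESNAMES = frozenset({"OH", "HO", "OXH"})

#: Factor multiplying the sum of covalent radii in the bond-inference cutoff.
BOND_INFERENCE_FACTOR = 1.6


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    formal_charge: int = 0
    is_ligand: bool = False
    vdw_radius: float = 1.70

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.residue_name, self.residue_number, self.chain_id)


class Topology:
    """Ordered atom list plus a set of unordered bonded serial pairs."""

    def __init__(
        self,
        atoms: list[AtomRecord],
        bonds: set[frozenset[int]] | None = None,
        source_path: str | None = None,
    ):
        if not atoms:
            raise ParseError("topology contains zero atoms")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            dup = sorted(s for s in set(serials) if serials.count(s) > 1)
            raise ParseError(f"duplicate atom serial(s): {dup[:5]}")
        self.atoms: list[AtomRecord] = list(atoms)
        self._index = {a.serial: i for i, a in enumerate(atoms)}
        self.bonds: set[frozenset[int]] = set()
        for b in bonds or ():
            pair = frozenset(b)
            if len(pair) != 2:
                raise ParseError(f"self-bond or malformed bond: {sorted(b)}")
            for s in pair:
                if s not in self._index:
                    raise ParseError(f"bond references missing serial {s}")
            self.bonds.add(pair)
        self.source_path = source_path
        self._neighbors: dict[int, tuple[int, ...]] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def index_of(self, serial: int) -> int:
        try:
            return self._index[serial]
        except KeyError:
            raise SelectionError(f"serial {serial} not in topology") from None

    def atom(self, serial: int) -> AtomRecord:
        return self.atoms[self.index_of(serial)]

    def neighbors(self, serial: int) -> tuple[int, ...]:
        if self._neighbors is None:
            nb: dict[int, list[int]] = {a.serial: [] for a in self.atoms}
            for pair in self.bonds:
                a, b = sorted(pair)
                nb[a].append(b)
                nb[b].append(a)
            self._neighbors = {s: tuple(sorted(v)) for s, v in nb.items()}
        return self._neighbors[serial]

    def serials(self) -> list[int]:
        return [a.serial for a in self.atoms]


@dataclass
class Frame:
    index: int
    coords: np.ndarray  # (n_atoms, 3) float64, Å
    time: float | None = None  # ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"frame {self.index}: coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError(f"frame {self.index}: non-finite coordinates")


class Trajectory:
    """Ordered frames over a fixed topology."""

    def __init__(self, topology: Topology, frames: list[Frame]):
        if not frames:
            raise ShapeError("trajectory must contain at least one frame")
        n = len(topology)
        for f in frames:
            if f.coords.shape[0] != n:
                raise ShapeError(
                    f"frame {f.index}: {f.coords.shape[0]} atoms, "
                    f"topology has {n}"
                )
        self.topology = topology
        self.frames = [
            Frame(i, f.coords, f.time) for i, f in enumerate(frames)
        ]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array (a copy)."""
        return np.stack([f.coords for f in self.frames])


def concat_trajectories(first: Trajectory, second: Trajectory) -> Trajectory:
    """Concatenate two trajectories that share a topology (frame-additive)."""
    if len(first.topology) != len(second.topology):
        raise ShapeError("cannot concatenate: atom counts differ")
    frames = [Frame(f.index, f.coords.copy(), f.time) for f in first.frames]
    offset = len(frames)
    frames += [
        Frame(offset + f.index, f.coords.copy(), f.time)
        for f in second.frames
    ]
    return Trajectory(first.topology, frames)


# ---------------------------------------------------------------------------
# Reading


def _is_ligand_record(record_type: str, resname: str, element: str) -> bool:
    if record_type != "HETATM":
        return False
    if resname in WATER_RESNAMES or resname in HYDROXIDE_RESNAMES:
        return False
    if element.upper() in METALS:
        return False
    return True


def _load_universe(*paths: str):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*paths)


def read_topology(path: str | Path, format: str = "pdb") -> Topology:
    """Read a PDB topology: atoms, bonds (CONECT or inferred), charges.

    Bonds come from CONECT records when present; otherwise they are inferred
    on the first model with the distance rule
    ``d < BOND_INFERENCE_FACTOR * (r_cov(a) + r_cov(b))``, with the extra
    constraints that hydrogens never bond to each other and each hydrogen
    bonds only to its nearest in-range heavy atom.
    """
    if format.lower() != "pdb":
        raise ParseError(f"unsupported topology format: {format}")
    path = str(path)
    try:
        u = _load_universe(path)
    except Exception as exc:  # MDAnalysis raises assorted types
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    n = len(u.atoms)
    if n == 0:
        raise ParseError(f"{path}: zero atoms")

    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    serials = [int(s) for s in u.atoms.ids]
    if len(set(serials)) != len(serials):
        raise ParseError(f"{path}: duplicate atom serials")
    chains = (
        u.atoms.chainIDs if hasattr(u.atoms, "chainIDs") else ["A"] * n
    )
    records = (
        u.atoms.record_types
        if hasattr(u.atoms, "record_types")
        else ["ATOM"] * n
    )
    if hasattr(u.atoms, "elements"):
        elements = [
            e.capitalize() if e.strip() else element_from_atom_name(nm)
            for e, nm in zip(u.atoms.elements, names)
        ]
    else:
        elements = [element_from_atom_name(nm) for nm in names]
    if hasattr(u.atoms, "formalcharges"):
        charges = [int(c) for c in u.atoms.formalcharges]
    else:
        charges = [0] * n

    atoms = []
    for i in range(n):
        atoms.append(
            AtomRecord(
                serial=serials[i],
                name=str(names[i]),
                element=elements[i],
                residue_name=str(resnames[i]),
                residue_number=int(resids[i]),
                chain_id=str(chains[i])[:1] or "A",
                formal_charge=charges[i],
                is_ligand=_is_ligand_record(
                    str(records[i]), str(resnames[i]), elements[i]
                ),
                vdw_radius=vdw_radius(elements[i]),
            )
        )

    bonds: set[frozenset[int]] = set()
    if hasattr(u.atoms, "bonds") and len(u.bonds) > 0:
        for b in u.bonds:
            i, j = (int(x) for x in b.atoms.ids)
            if i != j:
                bonds.add(frozenset((i, j)))
    else:
        coords = u.atoms.positions.astype(np.float64)
        bonds = _infer_bonds(atoms, coords)

    return Topology(atoms, bonds, source_path=path)


def _infer_bonds(
    atoms: list[AtomRecord], coords: np.ndarray
) -> set[frozenset[int]]:
    rcov = np.array([covalent_radius(a.element) for a in atoms])
    max_cut = BOND_INFERENCE_FACTOR * 2.0 * rcov.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    bonds: set[frozenset[int]] = set()
    h_best: dict[int, tuple[float, int]] = {}
    is_h = np.array([a.element.upper() == "H" for a in atoms])
    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > BOND_INFERENCE_FACTOR * (rcov[i] + rcov[j]) or d < 0.4:
            continue
        if is_h[i] and is_h[j]:
            continue
        if is_h[i] or is_h[j]:
            h, heavy = (i, j) if is_h[i] else (j, i)
            if h not in h_best or d < h_best[h][0]:
                h_best[h] = (d, heavy)
        else:
            bonds.add(frozenset((atoms[i].serial, atoms[j].serial)))
    for h, (_, heavy) in h_best.items():
        bonds.add(frozenset((atoms[h].serial, atoms[heavy].serial)))
    return bonds


def read_trajectory(
    topology: Topology, path: str | Path, format: str | None = None
) -> Trajectory:
    """Read a coordinate trajectory (multi-model PDB, DCD or XTC)."""
    path = str(path)
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "dcd", "xtc"}:
        raise ParseError(f"unsupported trajectory format: {fmt}")
    try:
        if fmt == "pdb":
            u = _load_universe(path)
        else:
            if topology.source_path is None:
                raise ParseError(
                    "DCD/XTC trajectories need a topology read from file"
                )
            u = _load_universe(topology.source_path, path)
    except ParseError:
        raise
    except Exception as exc:
        raise ShapeError(f"cannot read trajectory {path}: {exc}") from exc

    if len(u.atoms) != len(topology):
        raise ShapeError(
            f"{path}: {len(u.atoms)} atoms per frame, "
            f"topology has {len(topology)}"
        )
    frames = []
    has_time = fmt != "pdb"
    try:
        for ts in u.trajectory:
            frames.append(
                Frame(
                    index=len(frames),
                    coords=ts.positions.astype(np.float64),
                    time=float(ts.time) if has_time else None,
                )
            )
    except Exception as exc:
        raise ShapeError(
            f"{path}: error reading frame {len(frames)}: {exc}"
        ) from exc
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# Selections

_KEYWORDS = {
    "all",
    "calpha",
    "ligand",
    "protein",
    "water",
    "resname",
    "resnum",
    "name",
    "element",
    "serial",
    "and",
}


@dataclass(frozen=True)
class Selection:
    expression: str
    resolved: tuple[int, ...]  # serials, topology order
    indices: np.ndarray = field(compare=False, repr=False, default=None)

    def __len__(self) -> int:
        return len(self.resolved)


def _parse_ranges(tokens: list[str], what: str) -> list[tuple[int, int]]:
    out = []
    for tok in tokens:
        for part in tok.split(","):
            if not part:
                continue
            try:
                if "-" in part[1:]:
                    pos = part.index("-", 1)
                    out.append((int(part[:pos]), int(part[pos + 1 :])))
                else:
                    out.append((int(part), int(part)))
            except ValueError:
                raise SelectionError(
                    f"bad {what} range: {part!r}"
                ) from None
    if not out:
        raise SelectionError(f"{what} requires at least one value")
    return out


def resolve_selection(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression to an ordered list of serials.

    Grammar: clauses joined by ``and`` (all must hold). Clauses:
    ``all``, ``calpha``, ``ligand``, ``protein``, ``water``,
    ``resname N [N ...]``, ``name N [N ...]``, ``element E [E ...]``,
    ``resnum A[-B][,C-D ...]``, ``serial A[-B]``. Residue numbers are the
    file's own (1-based) numbering; ranges are inclusive.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    n = len(topology)
    mask = np.ones(n, dtype=bool)
    i = 0
    any_clause = False
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "and":
            i += 1
            continue
        if tok not in _KEYWORDS:
            raise SelectionError(f"unknown selection keyword: {tokens[i]!r}")
        any_clause = True
        if tok in {"all", "calpha", "ligand", "protein", "water"}:
            clause = np.zeros(n, dtype=bool)
            for k, a in enumerate(topology.atoms):
                if tok == "all":
                    clause[k] = True
                elif tok == "calpha":
                    clause[k] = (
                        a.name.strip() == "CA"
                        and a.residue_name in STANDARD_AA
                    )
                elif tok == "ligand":
                    clause[k] = a.is_ligand
                elif tok == "protein":
                    clause[k] = a.residue_name in STANDARD_AA
                elif tok == "water":
                    clause[k] = a.residue_name in WATER_RESNAMES
            mask &= clause
            i += 1
            continue
        # value-taking clauses
        vals = []
        j = i + 1
        while j < len(tokens) and tokens[j].lower() not in _KEYWORDS:
            vals.append(tokens[j])
            j += 1
        if not vals:
            raise SelectionError(f"{tok!r} requires a value")
        clause = np.zeros(n, dtype=bool)
        if tok in {"resname", "name", "element"}:
            wanted = {v.upper() for v in vals}
            for k, a in enumerate(topology.atoms):
                key = {
                    "resname": a.residue_name,
                    "name": a.name.strip(),
                    "element": a.element,
                }[tok].upper()
                clause[k] = key in wanted
        else:  # resnum / serial
            ranges = _parse_ranges(vals, tok)
            for k, a in enumerate(topology.atoms):
                v = a.residue_number if tok == "resnum" else a.serial
                clause[k] = any(lo <= v <= hi for lo, hi in ranges)
        mask &= clause
        i = j
    if not any_clause:
        raise SelectionError("selection has no clauses")
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        warnings.warn(
            f"selection {expression!r} matched no atoms", stacklevel=2
        )
    serials = tuple(topology.atoms[k].serial for k in idx)
    return Selection(expression=expression, resolved=serials, indices=idx)


def as_selection(topology: Topology, sel) -> Selection:
    """Accept either a Selection or an expression string."""
    if isinstance(sel, Selection):
        return sel
    return resolve_selection(topology, str(sel))


# ---------------------------------------------------------------------------
# Writing


def _format_charge(c: int) -> str:
    if c == 0:
        return "  "
    return f"{abs(c)}{'+' if c > 0 else '-'}"


def _pdb_atom_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz,
    occupancy: float = 1.00,
    bfactor: float = 0.00,
    element: str = "C",
    charge: int = 0,
) -> str:
    nm = name.strip()
    nm = nm if len(nm) >= 4 else f" {nm:<3}"
    serial = (serial - 1) % 99999 + 1
    resnum = (resnum - 1) % 9999 + 1
    return (
        f"{record:<6}{serial:>5} {nm:<4} {resname:<3} {chain:1}{resnum:>4}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}"
        f"{bfactor:6.2f}          {element.upper():>2}{_format_charge(charge)}"
    )


def write_pseudoatom_pdb(
    points,
    labels,
    path: str | Path,
    frame_indices=None,
) -> None:
    """Write feature-cloud points as pseudo-atom HETATM records.

    ``labels`` is one 3-character residue-name code per point (or a single
    code for all points); the B-factor column carries the frame index
    (modulo the column's width).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    npts = len(points)
    if isinstance(labels, str):
        labels = [labels] * npts
    if len(labels) != npts:
        raise ValueError("labels length must match points")
    if frame_indices is None:
        frame_indices = list(range(npts))
    lines = ["REMARK   dynophore feature point cloud"]
    for i, (p, lab, fr) in enumerate(zip(points, labels, frame_indices)):
        lines.append(
            _pdb_atom_line(
                "HETATM",
                i + 1,
                "PSD",
                str(lab)[:3].upper() or "UNK",
                "X",
                i + 1,
                p,
                bfactor=float(fr % 1000),
                element="C",
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_topology_pdb(
    topology: Topology, coords: np.ndarray, path: str | Path
) -> None:
    """Write a single-model PDB with CONECT records."""
    Path(path).write_text(
        "\n".join(_model_lines(topology, coords) + _conect_lines(topology))
        + "\nEND\n"
    )


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL block per frame)."""
    lines: list[str] = []
    for f in traj.frames:
        lines.append(f"MODEL     {f.index + 1:>4}")
        lines.extend(_model_lines(traj.topology, f.coords))
        lines.append("ENDMDL")
    lines.extend(_conect_lines(traj.topology))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _model_lines(topology: Topology, coords: np.ndarray) -> list[str]:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(topology), 3):
        raise ShapeError(
            f"coords shape {coords.shape} != ({len(topology)}, 3)"
        )
    out = []
    for a, xyz in zip(topology.atoms, coords):
        record = "HETATM" if (a.is_ligand or a.residue_name not in STANDARD_AA) else "ATOM"
        out.append(
            _pdb_atom_line(
                record,
                a.serial,
                a.name,
                a.residue_name,
                a.chain_id,
                a.residue_number,
                xyz,
                element=a.element,
                charge=a.formal_charge,
            )
        )
    return out


def _conect_lines(topology: Topology) -> list[str]:
    nb: dict[int, list[int]] = {}
    for pair in topology.bonds:
        a, b = sorted(pair)
        nb.setdefault(a, []).append(b)
    out = []
    for a in sorted(nb):
        partners = sorted(nb[a])
        for k in range(0, len(partners), 4):
            chunk = partners[k : k + 4]
            out.append(
                "CONECT"
                + f"{a:>5}"
                + "".join(f"{p:>5}" for p in chunk)
            )
    return out
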