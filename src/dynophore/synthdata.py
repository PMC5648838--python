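"""Deterministic toy receptor-ligand trajectories with scripted interactions.

The generator builds a small pseudo-receptor whose residues present the
partner motifs of a metalloenzyme active site (backbone acceptor, serine-like
donor/acceptor, two carboxylates, a guanidinium, a methyl side chain, two
metal cations and a hydroxide) on a ~25 Å circle, plus a floppy probe ligand
whose functional groups are re-positioned every frame so that a user-declared
schedule decides exactly which interactions are satisfied in which frames.

Active schedules place the group's interaction point at ``on_distance`` from
the partner's anchor (hydrogens re-aimed so D-H...A angles are ideal);
inactive schedules hold it at ``off_distance``, outside the criteria window.
Distances may carry truncated Gaussian jitter that can never leave the
window, so every dynophore statistic on the output is known by construction.
The ligand is geometrically idealized and its inter-group bonds stretch
freely between frames: interaction detection depends only on interatomic
geometry, not on conformational realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FeasibilityError
from .percept import FeatureType, InteractionCriteria
from .trajio import (
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
    write_topology_pdb,
    write_trajectory_pdb,
)
from .elements import vdw_radius

Z = np.array([0.0, 0.0, 1.0])

# ---------------------------------------------------------------------------
# Receptor sites

#: site label -> (resname, resnum, atom table). Atom table rows:
#: (name, element, offset, formal_charge) with offset expressed in the
#: site's local (u=outward radial, t=tangent, z) frame.
_SITE_ATOMS: dict[str, tuple[str, int, list]] = {
    "GLY10": ("GLY", 10, [
        ("CA", "C", (0.0, 0.0, 0.0), 0),
        ("C", "C", (1.2, 0.0, 0.0), 0),
        ("O", "O", (2.4, 0.0, 0.0), 0),
    ]),
    "SER137": ("SER", 137, [
        ("CA", "C", (0.0, 0.0, 0.0), 0),
        ("CB", "C", (1.5, 0.0, 0.0), 0),
        ("OG", "O", (2.9, 0.0, 0.0), 0),
        ("HG", "H", (2.9, 0.0, -0.96), 0),
    ]),
    "ASP183": ("ASP", 183, [
        ("CA", "C", (0.0, 0.0, 0.0), 0),
        ("CB", "C", (1.3, 0.0, 0.0), 0),
        ("CG", "C", (2.6, 0.0, 0.0), 0),
        ("OD1", "O", (3.18, 1.12, 0.0), 0),
        ("OD2", "O", (3.18, -1.12, 0.0), -1),
    ]),
    "GLU186": ("GLU", 186, [
        ("CA", "C", (0.0, 0.0, 0.0), 0),
        ("CB", "C", (1.3, 0.0, 0.0), 0),
        ("CD", "C", (2.6, 0.0, 0.0), 0),
        ("OE1", "O", (3.18, 1.12, 0.0), 0),
        ("OE2", "O", (3.18, -1.12, 0.0), -1),
    ]),
    "ARG21": ("ARG", 21, [
        ("CA", "C", (0.0, 0.0, 0.0), 0),
        ("CZ", "C", (2.4, 0.0, 0.0), 1),
        ("NE", "N", (1.07, 0.0, 0.0), 0),
        ("NH1", "N", (3.07, 1.15, 0.0), 0),
        ("NH2", "N", (3.07, -1.15, 0.0), 0),
        ("HE", "H", (1.07, 0.0, -1.01), 0),
        ("HH1", "H", (3.07, 1.15, -1.01), 0),
        ("HH2", "H", (3.07, -1.15, -1.01), 0),
    ]),
    "THR246": ("THR", 246, [
        ("CA", "C", (0.0, 0.0, 0.0), 0),
        ("CB", "C", (1.5, 0.0, 0.0), 0),
        ("CG2", "C", (3.0, 0.0, 0.0), 0),
    ]),
    "MN501": ("MN", 501, [("MN", "Mn", (1.0, 0.0, 0.0), 2)]),
    "MN502": ("MN", 502, [("MN", "Mn", (1.0, 0.0, 0.0), 2)]),
    "OH503": ("OH", 503, [
        ("O", "O", (1.0, 0.0, 0.0), -1),
        ("H1", "H", (1.0, 0.0, -0.96), 0),
    ]),
}

_SITE_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY10": [("CA", "C"), ("C", "O")],
    "SER137": [("CA", "CB"), ("CB", "OG"), ("OG", "HG")],
    "ASP183": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU186": [("CA", "CB"), ("CB", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "ARG21": [
        ("CZ", "NE"), ("CZ", "NH1"), ("CZ", "NH2"),
        ("NE", "HE"), ("NH1", "HH1"), ("NH2", "HH2"),
        ("CA", "NE"),
    ],
    "THR246": [("CA", "CB"), ("CB", "CG2")],
    "MN501": [],
    "MN502": [],
    "OH503": [("O", "H1")],
}

#: anchor atom (or group) per interaction role, by site
_SITE_ANCHORS: dict[str, dict[str, object]] = {
    "GLY10": {"acceptor": "O"},
    "SER137": {"acceptor": "OG", "donor": ("OG", "HG")},
    "ASP183": {"neg": ("OD1", "OD2"), "acceptor": "OD1"},
    "GLU186": {"neg": ("OE1", "OE2"), "acceptor": "OE1"},
    "ARG21": {"pos": ("CZ", "NE", "NH1", "NH2")},
    "THR246": {"hydrophobic": "CG2"},
    "MN501": {"pos": ("MN",)},
    "MN502": {"pos": ("MN",)},
    "OH503": {"neg": ("O",), "acceptor": "O", "donor": ("O", "H1")},
}

SITE_ORDER = list(_SITE_ATOMS)

_RECEPTOR_RADIUS = 25.0
_CLUSTER_SPACING = 5.0

# ---------------------------------------------------------------------------
# Ligand recipes


@dataclass(frozen=True)
class _LigandGroup:
    label: str
    atoms: tuple  # (name, element, local xyz, formal_charge)
    allowed: frozenset  # FeatureType values allowed for schedules
    donor_hydrogens: tuple[str, ...] = ()  # re-aimable H names, in order
    donor_heavy: str | None = None


_AMINO_ACID_GROUPS = (
    _LigandGroup(
        "amine",
        (
            ("N", "N", (0.0, 0.0, 0.0), 1),
            ("H1", "H", (-0.5, 0.71, 0.5), 0),
            ("H2", "H", (-0.5, -0.71, 0.5), 0),
            ("H3", "H", (-0.5, 0.0, -0.86), 0),
            ("CA", "C", (-1.47, 0.0, 0.0), 0),
        ),
        frozenset({FeatureType.HBD, FeatureType.PI}),
        donor_hydrogens=("H1", "H2", "H3"),
        donor_heavy="N",
    ),
    _LigandGroup(
        "carboxylate",
        (
            ("C", "C", (-0.6, 0.0, 0.0), 0),
            ("O1", "O", (0.0, 1.12, 0.0), -1),
            ("O2", "O", (0.0, -1.12, 0.0), 0),
        ),
        frozenset({FeatureType.NI}),
    ),
    _LigandGroup(
        "hydroxyl",
        (
            ("C5", "C", (-1.43, 0.0, 0.0), 0),
            ("O5", "O", (0.0, 0.0, 0.0), 0),
            ("H5", "H", (-0.33, 0.9, 0.0), 0),
        ),
        frozenset({FeatureType.HBD, FeatureType.HBA}),
        donor_hydrogens=("H5",),
        donor_heavy="O5",
    ),
    _LigandGroup(
        "tail",
        (
            ("C2", "C", (-0.9, 1.25, 0.0), 0),
            ("C3", "C", (0.0, 0.0, 0.0), 0),
            ("C4", "C", (-0.9, -1.25, 0.0), 0),
        ),
        frozenset({FeatureType.H}),
    ),
)

_AMINO_ACID_BONDS = [
    ("N", "H1"), ("N", "H2"), ("N", "H3"), ("N", "CA"),
    ("CA", "C"), ("CA", "C2"),
    ("C", "O1"), ("C", "O2"),
    ("C2", "C3"), ("C3", "C4"), ("C3", "C5"),
    ("C5", "O5"), ("O5", "H5"),
]


def _boronate_group() -> tuple[_LigandGroup, ...]:
    # tetrahedral borate: B plus three O-H, one carbon stub; the group's
    # reference point is the heavy-atom centroid of (B, O1, O2, O3)
    s = 1.0 / math.sqrt(3.0)
    dirs = {
        "O1": np.array([1.0, 1.0, 1.0]) * s,
        "O2": np.array([1.0, -1.0, -1.0]) * s,
        "O3": np.array([-1.0, 1.0, -1.0]) * s,
        "C1": np.array([-1.0, -1.0, 1.0]) * s,
    }
    b = -(1.48 / 4.0) * (dirs["O1"] + dirs["O2"] + dirs["O3"])
    atoms = [("B", "B", tuple(b), -1)]
    for name in ("O1", "O2", "O3"):
        o = b + 1.48 * dirs[name]
        atoms.append((name, "O", tuple(o), 0))
        h = o + 0.96 * dirs[name]
        atoms.append((f"H{name[-1]}", "H", tuple(h), 0))
    atoms.append(("C1", "C", tuple(b + 1.6 * dirs["C1"]), 0))
    return (
        _LigandGroup(
            "boronate",
            tuple(atoms),
            frozenset({FeatureType.NI, FeatureType.HBA}),
        ),
    )


_BORONATE_BONDS = [
    ("B", "O1"), ("B", "O2"), ("B", "O3"), ("B", "C1"),
    ("O1", "H1"), ("O2", "H2"), ("O3", "H3"),
]

LIGAND_RECIPES: dict[str, tuple[tuple[_LigandGroup, ...], list]] = {
    "amino_acid": (_AMINO_ACID_GROUPS, _AMINO_ACID_BONDS),
    "boronate": (_boronate_group(), _BORONATE_BONDS),
}


# ---------------------------------------------------------------------------
# Schedules and spec


@dataclass(frozen=True)
class InteractionSchedule:
    feature_type: FeatureType
    group: str  # ligand group label
    partner: str  # site label, e.g. "SER137"
    active_frames: frozenset[int]
    on_distance: float
    off_distance: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.feature_type.value, self.group, self.partner)


def parse_active_frames(value, n_frames: int) -> frozenset[int]:
    """Accept an iterable of ints, 'even'/'odd', 'all', or [start, stop)."""
    if isinstance(value, str):
        if value == "even":
            return frozenset(range(0, n_frames, 2))
        if value == "odd":
            return frozenset(range(1, n_frames, 2))
        if value == "all":
            return frozenset(range(n_frames))
        raise ValueError(f"unknown active_frames spec: {value!r}")
    if isinstance(value, dict):
        return frozenset(range(int(value["start"]), int(value["stop"])))
    return frozenset(int(v) for v in value)


@dataclass
class ToySpec:
    n_frames: int
    ligand: str = "amino_acid"
    schedules: list[InteractionSchedule] = field(default_factory=list)
    jitter_sigma: float = 0.0
    seed: int = 0
    rigid_tumble: bool = False
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)

    @classmethod
    def from_dict(cls, d: dict) -> "ToySpec":
        n = int(d["n_frames"])
        schedules = [
            InteractionSchedule(
                feature_type=FeatureType(s["feature_type"]),
                group=s["group"],
                partner=s["partner"],
                active_frames=parse_active_frames(s["active_frames"], n),
                on_distance=float(s["on_distance"]),
                off_distance=float(s["off_distance"]),
            )
            for s in d.get("schedules", [])
        ]
        criteria = InteractionCriteria.from_dict(d.get("criteria", {}))
        return cls(
            n_frames=n,
            ligand=d.get("ligand", "amino_acid"),
            schedules=schedules,
            jitter_sigma=float(d.get("jitter_sigma", 0.0)),
            seed=int(d.get("seed", 0)),
            rigid_tumble=bool(d.get("rigid_tumble", False)),
            criteria=criteria,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ToySpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _window(
    ftype: FeatureType, partner: str, criteria: InteractionCriteria
) -> tuple[float, float]:
    if ftype in (FeatureType.HBD, FeatureType.HBA):
        return (criteria.hbond_dist_min, criteria.hbond_dist_max)
    if ftype in (FeatureType.PI, FeatureType.NI):
        if partner.startswith("MN"):
            return (0.0, criteria.metal_coord_max)
        return (0.0, criteria.ionic_dist_max)
    return (0.0, criteria.hydrophobic_dist_max)


def _validate_spec(spec: ToySpec) -> None:
    groups = {g.label: g for g in LIGAND_RECIPES[spec.ligand][0]}
    seen = set()
    for s in spec.schedules:
        if s.key in seen:
            raise FeasibilityError(f"duplicate schedule {s.key}")
        seen.add(s.key)
        if s.group not in groups:
            raise FeasibilityError(
                f"unknown ligand group {s.group!r} for recipe {spec.ligand!r}"
            )
        if s.partner not in _SITE_ATOMS:
            raise FeasibilityError(f"unknown partner site {s.partner!r}")
        if s.feature_type not in groups[s.group].allowed:
            raise FeasibilityError(
                f"group {s.group!r} cannot carry a "
                f"{s.feature_type.value} schedule"
            )
        role = {
            FeatureType.HBD: "acceptor",
            FeatureType.HBA: "donor",
            FeatureType.PI: "neg",
            FeatureType.NI: "pos",
            FeatureType.H: "hydrophobic",
        }[s.feature_type]
        if role not in _SITE_ANCHORS[s.partner]:
            raise FeasibilityError(
                f"site {s.partner!r} offers no {role} anchor for "
                f"{s.feature_type.value}"
            )
        lo, hi = _window(s.feature_type, s.partner, spec.criteria)
        if not (lo < s.on_distance < hi):
            raise FeasibilityError(
                f"on_distance {s.on_distance} outside ({lo}, {hi}) "
                f"for {s.key}"
            )
        if s.off_distance < hi + 0.5:
            raise FeasibilityError(
                f"off_distance {s.off_distance} must exceed {hi} by >= 0.5 Å"
            )
        if not s.active_frames <= set(range(spec.n_frames)):
            raise FeasibilityError(f"active frames out of range for {s.key}")
        margin = min(
            s.on_distance - lo if lo > 0 else s.on_distance,
            hi - s.on_distance,
            s.off_distance - hi - 0.25,
        )
        if spec.jitter_sigma > 0.5 * margin:
            raise FeasibilityError(
                f"jitter_sigma {spec.jitter_sigma} exceeds half the "
                f"{margin:.2f} Å margin of {s.key}"
            )


# ---------------------------------------------------------------------------
# Layout


def _site_clusters(spec: ToySpec) -> list[list[str]]:
    """Union-find over sites that share a ligand group in the schedules."""
    parent = {s: s for s in SITE_ORDER}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_group: dict[str, list[str]] = {}
    for s in spec.schedules:
        by_group.setdefault(s.group, []).append(s.partner)
    for partners in by_group.values():
        for p in partners[1:]:
            parent[find(p)] = find(partners[0])
    clusters: dict[str, list[str]] = {}
    order = []
    for site in SITE_ORDER:
        root = find(site)
        if root not in clusters:
            clusters[root] = []
            order.append(root)
        clusters[root].append(site)
    return [clusters[r] for r in order]


def _layout_receptor(spec: ToySpec):
    """Place sites; return (atoms, bonds, coords, anchors, donor_h_index)."""
    clusters = _site_clusters(spec)
    n_clusters = len(clusters)
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    bonds: list[frozenset[int]] = []
    name_to_serial: dict[tuple[str, str], int] = {}
    serial = 0
    for ci, cluster in enumerate(clusters):
        theta = 2.0 * math.pi * ci / n_clusters
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        t = np.array([-math.sin(theta), math.cos(theta), 0.0])
        base = _RECEPTOR_RADIUS * u
        m = len(cluster)
        for j, site in enumerate(cluster):
            offset = (j - (m - 1) / 2.0) * _CLUSTER_SPACING
            origin = base + offset * t + (j % 2) * 1.0 * Z
            resname, resnum, table = _SITE_ATOMS[site]
            for name, element, (du, dt, dz), fc in table:
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_name=resname,
                        residue_number=resnum,
                        chain_id="A",
                        formal_charge=fc,
                        is_ligand=False,
                        vdw_radius=vdw_radius(element),
                    )
                )
                coords.append(origin + du * u + dt * t + dz * Z)
                name_to_serial[(site, name)] = serial
            for a, b in _SITE_BONDS[site]:
                bonds.append(
                    frozenset(
                        (name_to_serial[(site, a)], name_to_serial[(site, b)])
                    )
                )
    coords_arr = np.array(coords)

    def pos_of(site, name):
        return coords_arr[name_to_serial[(site, name)] - 1]

    anchors: dict[tuple[str, str], np.ndarray] = {}
    donor_h: dict[str, tuple[int, int]] = {}  # site -> (D serial, H serial)
    for site, roles in _SITE_ANCHORS.items():
        for role, spec_names in roles.items():
            if role == "donor":
                heavy, h = spec_names
                anchors[(site, role)] = pos_of(site, heavy)
                donor_h[site] = (
                    name_to_serial[(site, heavy)],
                    name_to_serial[(site, h)],
                )
            elif isinstance(spec_names, tuple):
                anchors[(site, role)] = np.mean(
                    [pos_of(site, n) for n in spec_names], axis=0
                )
            else:
                anchors[(site, role)] = pos_of(site, spec_names)
    return atoms, bonds, coords_arr, anchors, donor_h, name_to_serial


_ROLE_BY_TYPE = {
    FeatureType.HBD: "acceptor",
    FeatureType.HBA: "donor",
    FeatureType.PI: "neg",
    FeatureType.NI: "pos",
    FeatureType.H: "hydrophobic",
}


def _orientation(ex: np.ndarray) -> np.ndarray:
    ex = ex / np.linalg.norm(ex)
    helper = Z if abs(float(ex @ Z)) < 0.9 else np.array([0.0, 1.0, 0.0])
    ey = helper - (helper @ ex) * ex
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return np.column_stack([ex, ey, ez])


def _solve_position(
    constraints: list[tuple[np.ndarray, float]],
    park: np.ndarray,
    frame_index: int,
    group: str,
) -> np.ndarray:
    if not constraints:
        return park
    if len(constraints) == 1:
        anchor, r = constraints[0]
        u = anchor / np.linalg.norm(anchor)
        return anchor + r * u
    if len(constraints) == 2:
        (p1, r1), (p2, r2) = constraints
        dvec = p2 - p1
        d = float(np.linalg.norm(dvec))
        if d > r1 + r2 + 1e-9 or d < abs(r1 - r2) - 1e-9:
            raise FeasibilityError(
                f"frame {frame_index}: group {group!r} cannot satisfy "
                f"distances {r1:.2f}/{r2:.2f} to anchors {d:.2f} Å apart"
            )
        ex = dvec / d
        a = (r1**2 - r2**2 + d**2) / (2.0 * d)
        h = math.sqrt(max(r1**2 - a**2, 0.0))
        base = p1 + a * ex
        out = 0.5 * (p1 + p2)
        w = out - (out @ ex) * ex
        if np.linalg.norm(w) < 1e-8:
            w = Z - (Z @ ex) * ex
        w /= np.linalg.norm(w)
        return base + h * w
    raise FeasibilityError(
        f"frame {frame_index}: group {group!r} has "
        f"{len(constraints)} simultaneous distance constraints (max 2)"
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# Generation


def generate_toy_trajectory(
    spec: ToySpec, out_dir: str | Path | None = None
) -> tuple[Trajectory, dict]:
    """Build the scripted trajectory and its ground-truth statistics.

    Returns ``(trajectory, ground_truth)``; when ``out_dir`` is given,
    ``topology.pdb``, ``trajectory.pdb`` and ``ground_truth.json`` are
    written there as well.
    """
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    groups, lig_bonds = LIGAND_RECIPES[spec.ligand]
    (
        rec_atoms,
        rec_bonds,
        rec_coords,
        anchors,
        donor_h,
        _names,
    ) = _layout_receptor(spec)

    # ligand atoms appended after the receptor, one LIG residue
    atoms = list(rec_atoms)
    bonds = list(rec_bonds)
    serial = len(rec_atoms)
    lig_serial: dict[str, int] = {}
    group_atom_index: dict[str, list[int]] = {}
    for g in groups:
        group_atom_index[g.label] = []
        for name, element, _xyz, fc in g.atoms:
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name="LIG",
                    residue_number=900,
                    chain_id="A",
                    formal_charge=fc,
                    is_ligand=True,
                    vdw_radius=vdw_radius(element),
                )
            )
            lig_serial[name] = serial
            group_atom_index[g.label].append(serial - 1)
    for a, b in lig_bonds:
        bonds.append(frozenset((lig_serial[a], lig_serial[b])))
    topo = Topology(atoms, set(bonds))

    by_group: dict[str, list[InteractionSchedule]] = {}
    for s in spec.schedules:
        by_group.setdefault(s.group, []).append(s)
    parks = {
        g.label: np.array(
            [(i - (len(groups) - 1) / 2.0) * 4.0, 0.0, 8.0]
        )
        for i, g in enumerate(groups)
    }

    frames = []
    for fi in range(spec.n_frames):
        coords = np.zeros((len(atoms), 3))
        coords[: len(rec_atoms)] = rec_coords
        for g in groups:
            scheds = by_group.get(g.label, [])
            constraints = []
            actives = []
            for s in scheds:
                anchor = anchors[(s.partner, _ROLE_BY_TYPE[s.feature_type])]
                active = fi in s.active_frames
                target = s.on_distance if active else s.off_distance
                if spec.jitter_sigma > 0:
                    lo, hi = _window(s.feature_type, s.partner, spec.criteria)
                    margin = min(
                        target - lo if lo > 0 else target,
                        abs(hi - target) if active else target - hi - 0.25,
                    )
                    bound = min(3.0 * spec.jitter_sigma, 0.95 * margin)
                    target += float(
                        np.clip(
                            rng.normal(0.0, spec.jitter_sigma), -bound, bound
                        )
                    )
                constraints.append((anchor, target))
                if active:
                    actives.append(s)
            pos = _solve_position(
                constraints, parks[g.label], fi, g.label
            )
            primary = (
                anchors[
                    (actives[0].partner, _ROLE_BY_TYPE[actives[0].feature_type])
                ]
                if actives
                else (constraints[0][0] if constraints else pos + np.array([1.0, 0, 0]))
            )
            direction = primary - pos
            if np.linalg.norm(direction) < 1e-9:
                direction = np.array([1.0, 0.0, 0.0])
            rot = _orientation(direction)
            for row, (name, _el, local, _fc) in zip(
                group_atom_index[g.label], g.atoms
            ):
                coords[row] = pos + rot @ np.asarray(local, dtype=float)
            # re-aim hydrogens for the active H-bond schedules
            hbd_actives = [
                s for s in actives if s.feature_type is FeatureType.HBD
            ]
            if hbd_actives:
                if len(hbd_actives) > len(g.donor_hydrogens):
                    raise FeasibilityError(
                        f"frame {fi}: group {g.label!r} must donate to "
                        f"{len(hbd_actives)} partners but has "
                        f"{len(g.donor_hydrogens)} hydrogens"
                    )
                d_xyz = coords[topo.index_of(lig_serial[g.donor_heavy])]
                for s, hname in zip(hbd_actives, g.donor_hydrogens):
                    a = anchors[(s.partner, "acceptor")]
                    coords[topo.index_of(lig_serial[hname])] = (
                        d_xyz + 0.98 * (a - d_xyz) / np.linalg.norm(a - d_xyz)
                    )
            aimed_partner_h: set[str] = set()
            for s in actives:
                if s.feature_type is not FeatureType.HBA:
                    continue
                if s.partner in aimed_partner_h:
                    raise FeasibilityError(
                        f"frame {fi}: partner {s.partner!r} donor hydrogen "
                        "aimed at two acceptors"
                    )
                aimed_partner_h.add(s.partner)
                d_serial, h_serial = donor_h[s.partner]
                d_xyz = coords[topo.index_of(d_serial)]
                coords[topo.index_of(h_serial)] = (
                    d_xyz + 0.96 * (pos - d_xyz) / np.linalg.norm(pos - d_xyz)
                )
        if spec.rigid_tumble:
            rot = _random_rotation(rng)
            shift = rng.uniform(-10.0, 10.0, size=3)
            coords = coords @ rot.T + shift
        frames.append(Frame(fi, coords))

    traj = Trajectory(topo, frames)
    truth = _ground_truth(spec, groups, lig_serial)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_topology_pdb(topo, frames[0].coords, out / "topology.pdb")
        write_trajectory_pdb(traj, out / "trajectory.pdb")
        (out / "ground_truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True)
        )
    return traj, truth


def _expected_label(
    ftype: FeatureType, group: _LigandGroup, lig_serial: dict[str, int]
) -> str:
    """Superfeature label the perception module will assign."""
    if ftype is FeatureType.HBD:
        return f"HBD[{group.donor_heavy}]"
    names_by_serial = {v: k for k, v in lig_serial.items()}

    def join(names):
        serials = sorted(lig_serial[n] for n in names)
        return "-".join(names_by_serial[s] for s in serials)

    if group.label == "amine":
        return "PI[N]"
    if group.label == "carboxylate":
        return "NI[" + join(["O1", "O2"]) + "]"
    if group.label == "hydroxyl":
        return "HBA[O5]"
    if group.label == "tail":
        return "H[" + join(["C2", "C3", "C4"]) + "]"
    if group.label == "boronate":
        names = ["B", "O1", "O2", "O3"]
        return f"{ftype.value}[" + join(names) + "]"
    raise KeyError(group.label)


def _ground_truth(
    spec: ToySpec, groups, lig_serial: dict[str, int]
) -> dict:
    by_sf: dict[tuple[str, str], list[InteractionSchedule]] = {}
    for s in spec.schedules:
        by_sf.setdefault((s.feature_type.value, s.group), []).append(s)
    group_map = {g.label: g for g in groups}
    superfeatures = []
    for (ftype, glabel), scheds in sorted(by_sf.items()):
        occ = frozenset().union(*(s.active_frames for s in scheds))
        if not occ:
            continue
        partners = []
        for s in sorted(scheds, key=lambda x: x.partner):
            resname, resnum, _ = _SITE_ATOMS[s.partner]
            partners.append(
                {
                    "partner": s.partner,
                    "residue_name": resname,
                    "residue_number": resnum,
                    "frame_count": len(s.active_frames),
                    "frequency_pct": 100.0 * len(s.active_frames) / len(occ),
                }
            )
        superfeatures.append(
            {
                "feature_type": ftype,
                "group": glabel,
                "label": _expected_label(
                    FeatureType(ftype), group_map[glabel], lig_serial
                ),
                "occurrence_count": len(occ),
                "occurrence_frames": sorted(occ),
                "frequency_pct": 100.0 * len(occ) / spec.n_frames,
                "partners": partners,
            }
        )
    return {
        "n_frames": spec.n_frames,
        "ligand": spec.ligand,
        "seed": spec.seed,
        "jitter_sigma": spec.jitter_sigma,
        "rigid_tumble": spec.rigid_tumble,
        "superfeatures": superfeatures,
    }


# ---------------------------------------------------------------------------
# Volume phantoms


def generate_volume_phantom(
    radius: float = 10.0,
    occluders: list[tuple] | None = None,
    path: str | Path | None = None,
) -> Trajectory:
    """Single-frame system: a marker atom at the origin plus occluder atoms.

    The marker (HETATM, residue CEN) is the sphere center and is never an
    occluder; occluders are written as alanine CB pseudo-atoms so the
    default occluder rule (protein and ions occlude) picks them up.
    """
    atoms = [
        AtomRecord(
            serial=1,
            name="B",
            element="B",
            residue_name="CEN",
            residue_number=1,
            chain_id="A",
            is_ligand=True,
            vdw_radius=vdw_radius("B"),
        )
    ]
    coords = [np.zeros(3)]
    for i, (pos, element) in enumerate(occluders or []):
        atoms.append(
            AtomRecord(
                serial=i + 2,
                name="CB",
                element=element,
                residue_name="ALA",
                residue_number=2,
                chain_id="A",
                is_ligand=False,
                vdw_radius=vdw_radius(element),
            )
        )
        coords.append(np.asarray(pos, dtype=float))
    topo = Topology(atoms, set())
    traj = Trajectory(topo, [Frame(0, np.array(coords))])
    if path is not None:
        write_topology_pdb(topo, traj.frames[0].coords, path)
    return traj


def slab_occluders(
    radius: float = 10.0,
    spacing: float = 0.6,
    top: float = -1.682,
    element: str = "C",
) -> list[tuple]:
    """Occluders filling the half-space z < 0 under a sphere of ``radius``.

    The top layer sits one mean effective sphere height below z = 0
    (vdW radius minus the lattice's mean sagitta), so the occluded region's
    boundary averages out to the z = 0 plane.
    """
    r_atom = vdw_radius(element)
    xs = np.arange(-radius - 1.0, radius + 1.0 + spacing, spacing)
    zs = np.arange(top, -radius - r_atom - spacing, -spacing)
    out = []
    for z in zs:
        for x in xs:
            for y in xs:
                out.append((np.array([x, y, z]), element))
    return out
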