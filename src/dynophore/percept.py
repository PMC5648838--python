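"""Pharmacophore feature perception and per-frame interaction detection.

The ligand is decomposed into typed feature templates (H-bond donors and
acceptors, positive/negative ionizable groups, hydrophobic carbon sets) by a
rule table over elements, bonds and formal charges. The environment is
partitioned into per-residue partners (protein, metal, hydroxide, water,
other heteroatoms). Per frame, geometric criteria (heavy-atom distances,
D-H...A angles, charged-centroid distances) decide which template-partner
contacts are realized as interaction events.

All geometric thresholds live in :class:`InteractionCriteria` and are
configurable; the shipped defaults are standard literature values (H-bond
2.5-3.8 Å with a >= 130 deg angle, ionic 5.5 Å, hydrophobic 4.5 Å, metal
coordination 3.0 Å).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .elements import METALS
from .errors import PerceptionError
from .trajio import (
    Frame,
    HYDROXIDE_RESNAMES,
    STANDARD_AA,
    Topology,
    WATER_RESNAMES,
    as_selection,
)


class FeatureType(str, Enum):
    """Closed feature taxonomy with the conventional display colors."""

    HBD = "HBD"  # H-bond donor
    HBA = "HBA"  # H-bond acceptor
    PI = "PI"  # positive ionizable
    NI = "NI"  # negative ionizable
    H = "H"  # hydrophobic contact

    @property
    def color(self) -> str:
        return {
            FeatureType.HBD: "green",
            FeatureType.HBA: "red",
            FeatureType.PI: "blue",
            FeatureType.NI: "orange",
            FeatureType.H: "yellow",
        }[self]


@dataclass(frozen=True)
class FeatureTemplate:
    feature_type: FeatureType
    ligand_atoms: tuple[int, ...]  # heavy-atom serials, sorted
    hydrogens: tuple[int, ...] = ()  # attached H serials (HBD only)
    label: str = ""

    @property
    def key(self) -> tuple[str, tuple[int, ...]]:
        return (self.feature_type.value, self.ligand_atoms)


@dataclass(frozen=True)
class EnvironmentPartner:
    residue_name: str
    residue_number: int
    chain_id: str
    atom_serials: tuple[int, ...]
    partner_class: str  # protein | metal | hydroxide | water | other-het
    donors: tuple[tuple[int, tuple[int, ...]], ...] = ()
    acceptors: tuple[int, ...] = ()
    pos_groups: tuple[tuple[int, ...], ...] = ()
    neg_groups: tuple[tuple[int, ...], ...] = ()
    hydrophobic: tuple[int, ...] = ()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.residue_name, self.residue_number, self.chain_id)

    @property
    def label(self) -> str:
        return f"{self.residue_name}{self.residue_number}.{self.chain_id}"


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric interaction thresholds (distances in Å, angles in degrees)."""

    hbond_dist_min: float = 2.5
    hbond_dist_max: float = 3.8
    hbond_angle_min: float = 130.0
    ionic_dist_max: float = 5.5
    hydrophobic_dist_max: float = 4.5
    metal_coord_max: float = 3.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.hbond_dist_min >= self.hbond_dist_max:
            raise ValueError("hbond_dist_min must be < hbond_dist_max")

    def max_distance(self, ftype: FeatureType) -> float:
        if ftype in (FeatureType.HBD, FeatureType.HBA):
            return self.hbond_dist_max
        if ftype in (FeatureType.PI, FeatureType.NI):
            return max(self.ionic_dist_max, self.metal_coord_max)
        return self.hydrophobic_dist_max

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionCriteria":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown criteria keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "InteractionCriteria":
        """Read a flat ``key = value`` config file (# comments allowed)."""
        d = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            k, v = (s.strip() for s in line.split("=", 1))
            d[k] = v
        return cls.from_dict(d)


@dataclass(frozen=True)
class InteractionEvent:
    frame_index: int
    template: FeatureTemplate
    partner: EnvironmentPartner
    distance: float
    feature_centroid: np.ndarray = field(compare=False)


# ---------------------------------------------------------------------------
# Chemistry rules shared between ligand and environment perception


def _attached_hydrogens(topo: Topology, serial: int) -> tuple[int, ...]:
    return tuple(
        s for s in topo.neighbors(serial) if topo.atom(s).element.upper() == "H"
    )


def _degree(topo: Topology, serial: int) -> int:
    return len(topo.neighbors(serial))


def _heavy_neighbors(topo: Topology, serial: int) -> tuple[int, ...]:
    return tuple(
        s for s in topo.neighbors(serial) if topo.atom(s).element.upper() != "H"
    )


def _find_donors(
    topo: Topology, serials: list[int]
) -> list[tuple[int, tuple[int, ...]]]:
    """O/N atoms carrying at least one explicit hydrogen."""
    out = []
    for s in serials:
        if topo.atom(s).element.upper() in ("O", "N"):
            hs = _attached_hydrogens(topo, s)
            if hs:
                out.append((s, hs))
    return out


def _find_acceptors(topo: Topology, serials: list[int]) -> list[int]:
    """O and lone-pair-bearing N atoms that are not positively charged.

    Every O with non-positive formal charge accepts; N accepts only when its
    connectivity leaves a lone pair pointing outward (two or fewer bonds),
    which keeps amide and ammonium nitrogens out.
    """
    out = []
    for s in serials:
        a = topo.atom(s)
        el = a.element.upper()
        if a.formal_charge > 0:
            continue
        if el == "O":
            out.append(s)
        elif el == "N" and _degree(topo, s) <= 2:
            out.append(s)
    return out


def _find_charged_groups(
    topo: Topology, serials: list[int]
) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """(positive groups, negative groups) as tuples of heavy-atom serials."""
    sset = set(serials)
    pos: list[tuple[int, ...]] = []
    neg: list[tuple[int, ...]] = []
    claimed_pos: set[int] = set()
    claimed_neg: set[int] = set()

    def terminal_oxygens(center: int) -> list[int]:
        return [
            o
            for o in _heavy_neighbors(topo, center)
            if topo.atom(o).element.upper() == "O"
            and len(_heavy_neighbors(topo, o)) == 1
            and o in sset
        ]

    for s in serials:
        a = topo.atom(s)
        el = a.element.upper()
        if el == "C":
            n_nbrs = [
                x
                for x in _heavy_neighbors(topo, s)
                if topo.atom(x).element.upper() == "N" and x in sset
            ]
            # guanidinium / amidinium carbon: >= 2 nitrogen neighbors and a
            # formal positive charge anywhere in the group (3 N always counts)
            if len(n_nbrs) >= 2:
                charge = a.formal_charge + sum(
                    topo.atom(x).formal_charge for x in n_nbrs
                )
                if len(n_nbrs) == 3 or charge > 0:
                    grp = tuple(sorted([s, *n_nbrs]))
                    pos.append(grp)
                    claimed_pos.update(grp)
            term_o = terminal_oxygens(s)
            if len(term_o) == 2:
                grp = tuple(sorted(term_o))
                neg.append(grp)
                claimed_neg.update([s, *grp])
        elif el == "B":
            o_nbrs = [
                o
                for o in _heavy_neighbors(topo, s)
                if topo.atom(o).element.upper() == "O" and o in sset
            ]
            if a.formal_charge < 0 or _degree(topo, s) - len(
                _attached_hydrogens(topo, s)
            ) >= 4:
                grp = tuple(sorted([s, *o_nbrs]))
                neg.append(grp)
                claimed_neg.update(grp)
        elif el == "S":
            term_o = terminal_oxygens(s)
            if len(term_o) >= 3:
                grp = tuple(sorted([s, *term_o]))
                neg.append(grp)
                claimed_neg.update(grp)
        elif el == "P":
            term_o = terminal_oxygens(s)
            if len(term_o) >= 2:
                grp = tuple(sorted([s, *term_o]))
                neg.append(grp)
                claimed_neg.update(grp)

    for s in serials:
        a = topo.atom(s)
        el = a.element.upper()
        if el == "N" and s not in claimed_pos:
            if a.formal_charge > 0 or _degree(topo, s) == 4:
                pos.append((s,))
                claimed_pos.add(s)
        elif el == "O" and s not in claimed_neg:
            heavies = _heavy_neighbors(topo, s)
            if a.formal_charge < 0 and not heavies:
                neg.append((s,))  # hydroxide-style lone oxygen
        elif el.upper() in METALS:
            pos.append((s,))
    return pos, neg


def _find_hydrophobic(topo: Topology, serials: list[int]) -> list[int]:
    """C/S atoms bonded to nothing but C, H or S."""
    out = []
    for s in serials:
        el = topo.atom(s).element.upper()
        if el not in ("C", "S"):
            continue
        nbrs = topo.neighbors(s)
        if nbrs and all(
            topo.atom(x).element.upper() in ("C", "H", "S") for x in nbrs
        ):
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Ligand feature perception


def perceive_features(
    topology: Topology, ligand_selection
) -> list[FeatureTemplate]:
    """Type the ligand's pharmacophore feature templates.

    Rules: HBD per O/N-H group; HBA per lone-pair O/N (a tetrahedral borate
    is one grouped acceptor rather than three, matching how boronic-acid
    transition-state analogs are conventionally described); PI per
    protonated amine or guanidinium/amidinium group; NI per carboxylate,
    borate, sulfonate or phosphate group; hydrophobic per connected set of
    >= 3 apolar carbons.
    """
    sel = as_selection(topology, ligand_selection)
    serials = list(sel.resolved)
    if not serials:
        raise PerceptionError("ligand selection matched no atoms")
    heavy = [
        s for s in serials if topology.atom(s).element.upper() != "H"
    ]

    def aname(s: int) -> str:
        return topology.atom(s).name.strip()

    templates: list[FeatureTemplate] = []
    pos_groups, neg_groups = _find_charged_groups(topology, heavy)
    borate_oxygens: set[int] = set()
    borate_groups = []
    for grp in neg_groups:
        if any(topology.atom(s).element.upper() == "B" for s in grp):
            borate_groups.append(grp)
            borate_oxygens.update(
                s for s in grp if topology.atom(s).element.upper() == "O"
            )

    for s, hs in _find_donors(topology, heavy):
        templates.append(
            FeatureTemplate(
                FeatureType.HBD, (s,), hydrogens=hs, label=f"HBD[{aname(s)}]"
            )
        )
    for s in _find_acceptors(topology, heavy):
        if s in borate_oxygens:
            continue
        templates.append(
            FeatureTemplate(FeatureType.HBA, (s,), label=f"HBA[{aname(s)}]")
        )
    for grp in borate_groups:
        templates.append(
            FeatureTemplate(
                FeatureType.HBA,
                tuple(sorted(grp)),
                label="HBA[" + "-".join(aname(s) for s in sorted(grp)) + "]",
            )
        )
    for grp in pos_groups:
        templates.append(
            FeatureTemplate(
                FeatureType.PI,
                tuple(sorted(grp)),
                label="PI[" + "-".join(aname(s) for s in sorted(grp)) + "]",
            )
        )
    for grp in neg_groups:
        templates.append(
            FeatureTemplate(
                FeatureType.NI,
                tuple(sorted(grp)),
                label="NI[" + "-".join(aname(s) for s in sorted(grp)) + "]",
            )
        )
    # hydrophobic: connected components of apolar carbons, size >= 3
    hydro = [
        s
        for s in _find_hydrophobic(topology, heavy)
        if topology.atom(s).element.upper() == "C"
    ]
    hset = set(hydro)
    seen: set[int] = set()
    for s in hydro:
        if s in seen:
            continue
        comp, stack = [], [s]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            comp.append(cur)
            stack.extend(x for x in topology.neighbors(cur) if x in hset)
        if len(comp) >= 3:
            comp = sorted(comp)
            templates.append(
                FeatureTemplate(
                    FeatureType.H,
                    tuple(comp),
                    label="H[" + "-".join(aname(x) for x in comp) + "]",
                )
            )
    templates.sort(key=lambda t: (t.feature_type.value, t.ligand_atoms))
    return templates


def classify_environment(
    topology: Topology, ligand_selection
) -> list[EnvironmentPartner]:
    """Partition all non-ligand residues into typed interaction partners."""
    sel = as_selection(topology, ligand_selection)
    ligand = set(sel.resolved)
    by_res: dict[tuple[str, int, str], list[int]] = {}
    order: list[tuple[str, int, str]] = []
    for a in topology.atoms:
        if a.serial in ligand:
            continue
        if a.residue_key not in by_res:
            by_res[a.residue_key] = []
            order.append(a.residue_key)
        by_res[a.residue_key].append(a.serial)

    partners = []
    for key in order:
        serials = by_res[key]
        resname, resnum, chain = key
        elements = {topology.atom(s).element.upper() for s in serials}
        if resname in WATER_RESNAMES:
            cls = "water"
        elif elements and elements <= METALS:
            cls = "metal"
        elif resname in HYDROXIDE_RESNAMES or elements <= {"O", "H"}:
            cls = "hydroxide"
        elif resname in STANDARD_AA:
            cls = "protein"
        else:
            cls = "other-het"
        heavy = [
            s for s in serials if topology.atom(s).element.upper() != "H"
        ]
        pos, neg = _find_charged_groups(topology, heavy)
        if cls == "hydroxide" and not neg:
            neg = [tuple(heavy)]
        partners.append(
            EnvironmentPartner(
                residue_name=resname,
                residue_number=resnum,
                chain_id=chain,
                atom_serials=tuple(serials),
                partner_class=cls,
                donors=tuple(_find_donors(topology, heavy)),
                acceptors=tuple(_find_acceptors(topology, heavy)),
                pos_groups=tuple(pos),
                neg_groups=tuple(neg),
                hydrophobic=tuple(_find_hydrophobic(topology, heavy)),
            )
        )
    return partners


# ---------------------------------------------------------------------------
# Per-frame detection


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


_warned_no_hydrogen: set[tuple] = set()


def _hbond_match(
    xyz,
    donor: int,
    donor_hs: tuple[int, ...],
    acceptor_xyz: np.ndarray,
    criteria: InteractionCriteria,
    warn_key: tuple,
) -> float | None:
    """Distance if the D(-H)...A geometry qualifies, else None."""
    d = float(np.linalg.norm(xyz(donor) - acceptor_xyz))
    if not (criteria.hbond_dist_min <= d <= criteria.hbond_dist_max):
        return None
    if not donor_hs:
        if warn_key not in _warned_no_hydrogen:
            _warned_no_hydrogen.add(warn_key)
            warnings.warn(
                f"donor {warn_key} has no explicit hydrogen; "
                "using heavy-atom distance only",
                stacklevel=2,
            )
        return d
    best = max(
        _angle_deg(xyz(donor), xyz(h), acceptor_xyz) for h in donor_hs
    )
    return d if best >= criteria.hbond_angle_min else None


def detect_frame_interactions(
    topology: Topology,
    frame: Frame,
    templates: list[FeatureTemplate],
    partners: list[EnvironmentPartner],
    criteria: InteractionCriteria | None = None,
    include_water: bool = False,
    neighbor_list: bool = True,
) -> list[InteractionEvent]:
    """Detect all template-partner interaction events in one frame.

    At most one event per (template, partner) is emitted, carrying the
    minimal qualifying distance. With ``neighbor_list`` a KD-tree prescreen
    skips partners entirely out of range; the result is identical to the
    brute-force all-pairs scan.
    """
    criteria = criteria or InteractionCriteria()
    coords = frame.coords

    def xyz(serial: int) -> np.ndarray:
        return coords[topology.index_of(serial)]

    def centroid(serials) -> np.ndarray:
        return np.mean([xyz(s) for s in serials], axis=0)

    active = [
        p
        for p in partners
        if include_water or p.partner_class != "water"
    ]
    if neighbor_list and active:
        # prescreen margin covers the largest charged-group centroid offset
        # on both sides (< 1.75 Å each), so no qualifying pair is pruned
        cut = (
            max(
                criteria.hbond_dist_max,
                criteria.ionic_dist_max,
                criteria.hydrophobic_dist_max,
                criteria.metal_coord_max,
            )
            + 3.5
        )
        lig_serials = sorted(
            {s for t in templates for s in (*t.ligand_atoms, *t.hydrogens)}
        )
        if lig_serials:
            lig_xyz = np.array([xyz(s) for s in lig_serials])
            tree = cKDTree(lig_xyz)
            kept = []
            for p in active:
                p_xyz = np.array([xyz(s) for s in p.atom_serials])
                if tree.query_ball_point(p_xyz, cut, return_length=True).any():
                    kept.append(p)
            active = kept

    events: list[InteractionEvent] = []
    for t in templates:
        t_centroid = centroid(t.ligand_atoms)
        for p in active:
            best: float | None = None
            if t.feature_type is FeatureType.HBD:
                donor = t.ligand_atoms[0]
                for acc in p.acceptors:
                    d = _hbond_match(
                        xyz, donor, t.hydrogens, xyz(acc), criteria,
                        ("ligand", donor),
                    )
                    if d is not None and (best is None or d < best):
                        best = d
            elif t.feature_type is FeatureType.HBA:
                a_xyz = t_centroid
                for donor, hs in p.donors:
                    d = _hbond_match(
                        xyz, donor, hs, a_xyz, criteria, (p.key, donor)
                    )
                    if d is not None and (best is None or d < best):
                        best = d
            elif t.feature_type is FeatureType.PI:
                for grp in p.neg_groups:
                    d = float(np.linalg.norm(t_centroid - centroid(grp)))
                    if d <= criteria.ionic_dist_max and (
                        best is None or d < best
                    ):
                        best = d
            elif t.feature_type is FeatureType.NI:
                for grp in p.pos_groups:
                    is_metal = all(
                        topology.atom(s).element.upper() in METALS
                        for s in grp
                    )
                    cutoff = (
                        criteria.metal_coord_max
                        if is_metal
                        else criteria.ionic_dist_max
                    )
                    d = float(np.linalg.norm(t_centroid - centroid(grp)))
                    if d <= cutoff and (best is None or d < best):
                        best = d
            else:  # hydrophobic
                for c in t.ligand_atoms:
                    c_xyz = xyz(c)
                    for h_atom in p.hydrophobic:
                        d = float(np.linalg.norm(c_xyz - xyz(h_atom)))
                        if d <= criteria.hydrophobic_dist_max and (
                            best is None or d < best
                        ):
                            best = d
            if best is not None:
                events.append(
                    InteractionEvent(
                        frame_index=frame.index,
                        template=t,
                        partner=p,
                        distance=best,
                        feature_centroid=t_centroid,
                    )
                )
    return events
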