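"""Rigid-body superposition and trajectory metrics.

Implements least-squares Cα superposition (Kabsch, via SVD with a proper
rotation constraint), per-frame RMSD, per-atom RMSF, and a grid-based
sphere-bounded binding-pocket volume in the POVME style: grid points inside
an inclusion sphere count toward the volume unless they fall inside any
occluding atom's van der Waals sphere (optionally inflated by a probe
radius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, SelectionError
from .trajio import (
    Frame,
    Selection,
    Topology,
    Trajectory,
    WATER_RESNAMES,
    as_selection,
)


@dataclass(frozen=True)
class RigidTransform:
    """x' = rotation @ x + translation (column-vector convention)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> RigidTransform:
    """Proper rotation + translation minimizing RMSD of mobile onto reference.

    Standard Kabsch algorithm: SVD of the covariance of the centered point
    sets, with the sign of the smallest singular vector flipped when needed
    to keep the rotation proper (det = +1, no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    # collinearity check: rank of centered mobile must be >= 2
    if np.linalg.matrix_rank(np.vstack([x, y]), tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point configuration")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cr - rot @ cm
    return RigidTransform(rot, trans)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def align_trajectory(
    traj: Trajectory,
    fit_selection: str | Selection = "calpha",
    reference_frame: int = 0,
) -> Trajectory:
    """Superpose every frame's fit-selection atoms onto the reference frame.

    The whole frame (ligand included) moves with its fitted transform, so
    the returned trajectory is expressed in the reference frame's
    coordinate system.
    """
    sel = as_selection(traj.topology, fit_selection)
    if len(sel) < 3:
        raise GeometryError(
            f"fit selection {sel.expression!r} has {len(sel)} atoms; need >= 3"
        )
    idx = sel.indices
    ref = traj.frames[reference_frame].coords[idx]
    frames = []
    for f in traj.frames:
        try:
            t = kabsch_superpose(f.coords[idx], ref)
        except GeometryError as exc:
            raise GeometryError(f"frame {f.index}: {exc}") from exc
        frames.append(Frame(f.index, t.apply(f.coords), f.time))
    return Trajectory(traj.topology, frames)


def compute_rmsd(
    traj: Trajectory,
    selection: str | Selection,
    reference_frame: int = 0,
    prefit: bool = True,
    fit_selection: str | Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) over the selection, after an optional rigid pre-fit.

    By default the pre-fit uses the measured selection itself (g_rms style);
    pass ``fit_selection`` to fit on a different atom set, e.g. fit on Cα
    while measuring the ligand.
    """
    sel = as_selection(traj.topology, selection)
    if len(sel) == 0:
        raise SelectionError("RMSD selection matched no atoms")
    work = traj
    if prefit:
        work = align_trajectory(
            traj, fit_selection or sel, reference_frame=reference_frame
        )
    idx = sel.indices
    ref = work.frames[reference_frame].coords[idx]
    return np.array(
        [rmsd_between(f.coords[idx], ref) for f in work.frames]
    )


def compute_rmsf(
    traj: Trajectory,
    selection: str | Selection,
    prefit: bool = True,
) -> np.ndarray:
    """Per-atom RMS fluctuation about the time-average position (Å)."""
    if traj.n_frames < 2:
        raise GeometryError("RMSF undefined for a single frame")
    sel = as_selection(traj.topology, selection)
    if len(sel) == 0:
        raise SelectionError("RMSF selection matched no atoms")
    work = align_trajectory(traj, sel) if prefit else traj
    coords = work.coords_array()[:, sel.indices, :]
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def rmsf_by_residue(
    topology: Topology, selection: str | Selection, rmsf: np.ndarray
) -> list[tuple[tuple[str, int, str], float]]:
    """Reduce per-atom RMSF to per-residue means over the selected atoms."""
    sel = as_selection(topology, selection)
    by_res: dict[tuple[str, int, str], list[float]] = {}
    order: list[tuple[str, int, str]] = []
    for serial, value in zip(sel.resolved, rmsf):
        key = topology.atom(serial).residue_key
        if key not in by_res:
            by_res[key] = []
            order.append(key)
        by_res[key].append(float(value))
    return [(key, float(np.mean(by_res[key]))) for key in order]


# ---------------------------------------------------------------------------
# Pocket volume


@dataclass
class VolumeGrid:
    center: np.ndarray
    radius: float
    spacing: float
    points: np.ndarray  # (n, 3) grid points inside the sphere
    occupancy: np.ndarray  # bool per point; True = occluded by an atom

    @property
    def volume(self) -> float:
        """Unoccluded volume in ų."""
        return float(self.spacing**3 * np.count_nonzero(~self.occupancy))


def _default_occluder_indices(
    topology: Topology, center_serial: int
) -> np.ndarray:
    """Protein and ion atoms occlude; ligand and water do not."""
    keep = []
    for i, a in enumerate(topology.atoms):
        if a.serial == center_serial:
            continue
        if a.is_ligand or a.residue_name in WATER_RESNAMES:
            continue
        keep.append(i)
    return np.array(keep, dtype=int)


def pocket_volume_grid(
    topology: Topology,
    frame: Frame,
    center_serial: int,
    radius: float = 10.0,
    spacing: float = 0.5,
    probe: float = 0.0,
    occluder_selection: str | Selection | None = None,
) -> VolumeGrid:
    """Build the occupancy grid for a sphere-bounded pocket volume."""
    if spacing <= 0 or spacing > radius / 5:
        raise GeometryError("spacing must be in (0, radius/5]")
    center = frame.coords[topology.index_of(center_serial)]

    half = int(np.floor(radius / spacing))
    axis = np.arange(-half, half + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius] + center

    if occluder_selection is not None:
        occ_idx = as_selection(topology, occluder_selection).indices
        occ_idx = occ_idx[
            np.array(
                [topology.atoms[i].serial != center_serial for i in occ_idx],
                dtype=bool,
            )
        ]
    else:
        occ_idx = _default_occluder_indices(topology, center_serial)

    occupancy = np.zeros(len(pts), dtype=bool)
    if occ_idx.size:
        atom_xyz = frame.coords[occ_idx]
        radii = np.array(
            [topology.atoms[i].vdw_radius for i in occ_idx]
        ) + probe
        # only atoms whose sphere can reach the inclusion sphere matter
        near = np.linalg.norm(atom_xyz - center, axis=1) <= radius + radii
        atom_xyz, radii = atom_xyz[near], radii[near]
        if len(atom_xyz):
            tree = cKDTree(pts)
            for xyz, r in zip(atom_xyz, radii):
                occupancy[tree.query_ball_point(xyz, r)] = True
    return VolumeGrid(
        center=center,
        radius=radius,
        spacing=spacing,
        points=pts,
        occupancy=occupancy,
    )


def pocket_volume(
    topology: Topology,
    frame: Frame,
    center_serial: int,
    radius: float = 10.0,
    spacing: float = 0.5,
    probe: float = 0.0,
    occluder_selection: str | Selection | None = None,
) -> float:
    """Sphere-bounded unoccluded pocket volume (ų) for one frame."""
    return pocket_volume_grid(
        topology,
        frame,
        center_serial,
        radius=radius,
        spacing=spacing,
        probe=probe,
        occluder_selection=occluder_selection,
    ).volume
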