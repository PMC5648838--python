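import math

import numpy as np
import pytest

from dynophore.errors import GeometryError
from dynophore.geometry import (
    align_trajectory,
    compute_rmsd,
    compute_rmsf,
    kabsch_superpose,
    pocket_volume,
    rmsd_between,
)
from dynophore.synthdata import generate_volume_phantom, slab_occluders
from tests.conftest import make_topology, make_trajectory

SPHERE_VOL = 4.0 / 3.0 * math.pi * 10.0**3


def rotation_z(deg):
    a = math.radians(deg)
    return np.array(
        [[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]]
    )


def grid_oracle_min_rmsd(mobile, reference, coarse=24, refine_levels=4):
    """Best superposition RMSD by nested Euler-angle grid search.

    Independent of the SVD path: rotations are enumerated on a grid that is
    recursively refined around the running best, translations solved by
    centroid matching.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def euler(a, b, c):
        ca, sa, cb, sb, cc, sc = (
            math.cos(a), math.sin(a), math.cos(b), math.sin(b),
            math.cos(c), math.sin(c),
        )
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        return rz1 @ ry @ rz2

    best = (np.inf, (0.0, 0.0, 0.0))
    centers = [(0.0, math.pi / 2, 0.0)]
    widths = (math.pi, math.pi / 2, math.pi)
    steps = coarse
    for level in range(refine_levels):
        c0 = best[1] if level else centers[0]
        grids = [
            np.linspace(c - w, c + w, steps)
            for c, w in zip(c0, widths)
        ]
        for a in grids[0]:
            for b in grids[1]:
                for c in grids[2]:
                    r = rmsd_between(mob @ euler(a, b, c).T, ref)
                    if r < best[0]:
                        best = (r, (a, b, c))
        widths = tuple(2.2 * w / steps for w in widths)
        steps = 9
    return best[0]


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        t = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_rigid_motion_fully_removed(self, random_coords_rng):
        pts = random_coords_rng.normal(size=(8, 3)) * 3
        ref = pts @ rotation_z(90).T + np.array([5.0, 0, 0])
        t = kabsch_superpose(pts, ref)
        assert rmsd_between(t.apply(pts), ref) < 1e-9
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_inverse_roundtrip(self, random_coords_rng):
        pts = random_coords_rng.normal(size=(5, 3))
        ref = random_coords_rng.normal(size=(5, 3))
        t = kabsch_superpose(pts, ref)
        np.testing.assert_allclose(
            t.inverse().apply(t.apply(pts)), pts, atol=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(6, 3)) * 2.0
        reference = rng.normal(size=(6, 3)) * 2.0
        t = kabsch_superpose(mobile, reference)
        kabsch_rmsd = rmsd_between(t.apply(mobile), reference)
        oracle = grid_oracle_min_rmsd(mobile, reference)
        assert kabsch_rmsd <= oracle + 1e-9
        assert abs(kabsch_rmsd - oracle) < 1e-3


def _rigid_tumble_traj(rng, n_atoms=6, n_frames=5):
    topo = make_topology(
        [
            (i + 1, "CA", "C", "GLY", i + 1, "A", 0, False)
            for i in range(n_atoms)
        ]
    )
    base = rng.normal(size=(n_atoms, 3)) * 4
    stack = []
    for _ in range(n_frames):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        stack.append(base @ rot.T + rng.uniform(-8, 8, 3))
    return make_trajectory(topo, stack)


class TestAlignment:
    def test_tumbling_rigid_body_collapses(self, random_coords_rng):
        traj = _rigid_tumble_traj(random_coords_rng)
        aligned = align_trajectory(traj, "all")
        ref = aligned.frames[0].coords
        for f in aligned.frames:
            np.testing.assert_allclose(f.coords, ref, atol=1e-6)

    def test_idempotent(self, random_coords_rng):
        traj = _rigid_tumble_traj(random_coords_rng)
        once = align_trajectory(traj, "all")
        twice = align_trajectory(once, "all")
        np.testing.assert_allclose(
            twice.coords_array(), once.coords_array(), atol=1e-6
        )

    def test_alignment_never_increases_fit_rmsd(self, random_coords_rng):
        traj = _rigid_tumble_traj(random_coords_rng)
        # add internal motion on top of the tumble
        noisy = make_trajectory(
            traj.topology,
            [
                f.coords + random_coords_rng.normal(size=f.coords.shape) * 0.5
                for f in traj.frames
            ],
        )
        aligned = align_trajectory(noisy, "all")
        ref_before = noisy.frames[0].coords
        ref_after = aligned.frames[0].coords
        for fb, fa in zip(noisy.frames, aligned.frames):
            assert (
                rmsd_between(fa.coords, ref_after)
                <= rmsd_between(fb.coords, ref_before) + 1e-9
            )


class TestRmsdRmsf:
    def _static(self, rng, n_frames=4):
        topo = make_topology(
            [(i + 1, "CA", "C", "GLY", i + 1, "A", 0, False) for i in range(5)]
        )
        base = rng.normal(size=(5, 3))
        return make_trajectory(topo, [base.copy() for _ in range(n_frames)])

    def test_static_rmsd_zero(self, random_coords_rng):
        traj = self._static(random_coords_rng)
        np.testing.assert_allclose(compute_rmsd(traj, "all"), 0.0, atol=1e-12)

    def test_single_atom_displacement_closed_form(self, random_coords_rng):
        traj = self._static(random_coords_rng, n_frames=2)
        coords = traj.frames[1].coords.copy()
        coords[2, 0] += 2.0
        traj = make_trajectory(traj.topology, [traj.frames[0].coords, coords])
        rmsd = compute_rmsd(traj, "serial 3", prefit=False)
        assert rmsd[0] == 0.0
        assert rmsd[1] == pytest.approx(2.0)

    def test_rmsd_matches_naive_formula(self, random_coords_rng):
        topo = make_topology(
            [(i + 1, "CA", "C", "GLY", i + 1, "A", 0, False) for i in range(7)]
        )
        stack = random_coords_rng.normal(size=(6, 7, 3)) * 3
        traj = make_trajectory(topo, stack)
        got = compute_rmsd(traj, "all", prefit=False)
        expected = [
            math.sqrt(np.mean(np.sum((c - stack[0]) ** 2, axis=1)))
            for c in stack
        ]
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_static_rmsf_zero(self, random_coords_rng):
        traj = self._static(random_coords_rng)
        np.testing.assert_allclose(compute_rmsf(traj, "all"), 0.0, atol=1e-12)

    def test_alternating_atom_closed_form(self, random_coords_rng):
        traj = self._static(random_coords_rng, n_frames=4)
        stack = traj.coords_array()
        stack[:, 1, 0] += np.array([1.0, -1.0, 1.0, -1.0])
        traj = make_trajectory(traj.topology, stack)
        rmsf = compute_rmsf(traj, "all", prefit=False)
        assert rmsf[1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.delete(rmsf, 1), 0.0, atol=1e-12)

    def test_rmsf_matches_naive_formula(self, random_coords_rng):
        topo = make_topology(
            [(i + 1, "CA", "C", "GLY", i + 1, "A", 0, False) for i in range(5)]
        )
        stack = random_coords_rng.normal(size=(8, 5, 3))
        traj = make_trajectory(topo, stack)
        got = compute_rmsf(traj, "all", prefit=False)
        mean = stack.mean(axis=0)
        expected = np.sqrt(
            np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0)
        )
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_rmsf_invariant_under_global_rigid_motion(self, random_coords_rng):
        topo = make_topology(
            [(i + 1, "CA", "C", "GLY", i + 1, "A", 0, False) for i in range(5)]
        )
        stack = random_coords_rng.normal(size=(6, 5, 3)) * 2
        traj = make_trajectory(topo, stack)
        moved = make_trajectory(
            topo, stack @ rotation_z(37).T + np.array([3.0, -2.0, 8.0])
        )
        np.testing.assert_allclose(
            compute_rmsf(traj, "all"), compute_rmsf(moved, "all"), atol=1e-6
        )

    def test_single_frame_rmsf_error(self, random_coords_rng):
        traj = self._static(random_coords_rng, n_frames=1)
        with pytest.raises(GeometryError):
            compute_rmsf(traj, "all")


class TestPocketVolume:
    def test_empty_sphere_near_analytic(self):
        ph = generate_volume_phantom()
        v = pocket_volume(ph.topology, ph.frames[0], 1)
        assert v == pytest.approx(SPHERE_VOL, rel=0.02)

    def test_fully_buried_is_zero(self):
        grid = np.arange(-11.5, 12.0, 1.5)
        occ = [
            (np.array([x, y, z]), "C")
            for x in grid
            for y in grid
            for z in grid
        ]
        ph = generate_volume_phantom(occluders=occ)
        assert pocket_volume(ph.topology, ph.frames[0], 1) == 0.0

    def test_half_space_slab(self):
        ph = generate_volume_phantom(occluders=slab_occluders())
        v = pocket_volume(ph.topology, ph.frames[0], 1)
        assert v == pytest.approx(SPHERE_VOL / 2, rel=0.03)

    def test_single_occluder_matches_fine_grid(self):
        ph = generate_volume_phantom(occluders=[(np.array([0.0, 0, 0]), "C")])
        coarse = pocket_volume(ph.topology, ph.frames[0], 1, spacing=0.5)
        fine = pocket_volume(ph.topology, ph.frames[0], 1, spacing=0.1)
        assert coarse == pytest.approx(fine, rel=0.03)

    def test_monotone_under_added_occluders(self):
        rng = np.random.default_rng(3)
        positions = rng.uniform(-8, 8, size=(20, 3))
        last = np.inf
        for k in (0, 5, 10, 20):
            ph = generate_volume_phantom(
                occluders=[(p, "C") for p in positions[:k]]
            )
            v = pocket_volume(ph.topology, ph.frames[0], 1)
            assert v <= last
            last = v

    def test_spacing_validation(self):
        ph = generate_volume_phantom()
        with pytest.raises(GeometryError):
            pocket_volume(ph.topology, ph.frames[0], 1, spacing=3.0)
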