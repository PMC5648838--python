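import numpy as np
import pytest

from dynophore.errors import PerceptionError
from dynophore.percept import (
    FeatureType,
    InteractionCriteria,
    classify_environment,
    detect_frame_interactions,
    perceive_features,
)
from dynophore.synthdata import ToySpec, generate_toy_trajectory
from dynophore.trajio import Frame, Topology
from tests.conftest import hbond_schedule, make_topology


def _toy_topology(ligand="amino_acid"):
    spec = ToySpec(n_frames=1, ligand=ligand, seed=0)
    traj, _ = generate_toy_trajectory(spec)
    return traj


class TestPerceiveFeatures:
    def test_boronate_probe_taxonomy(self):
        traj = _toy_topology("boronate")
        templates = perceive_features(traj.topology, "resname LIG")
        by_type = {}
        for t in templates:
            by_type.setdefault(t.feature_type, []).append(t)
        assert len(by_type[FeatureType.HBD]) == 3
        assert len(by_type[FeatureType.HBA]) == 1
        assert len(by_type[FeatureType.NI]) == 1
        assert set(by_type) == {FeatureType.HBD, FeatureType.HBA, FeatureType.NI}
        # borate acceptor and charge are grouped on the whole B(OH)3 moiety
        assert len(by_type[FeatureType.HBA][0].ligand_atoms) == 4
        assert by_type[FeatureType.NI][0].ligand_atoms == by_type[
            FeatureType.HBA
        ][0].ligand_atoms

    def test_amino_acid_probe_taxonomy(self):
        traj = _toy_topology("amino_acid")
        templates = perceive_features(traj.topology, "resname LIG")
        labels = {t.label for t in templates}
        assert "PI[N]" in labels  # protonated amine
        assert "HBD[N]" in labels
        assert "HBD[O5]" in labels and "HBA[O5]" in labels  # hydroxyl
        assert any(
            t.feature_type is FeatureType.NI and len(t.ligand_atoms) == 2
            for t in templates
        )  # carboxylate: both oxygens, one template
        assert any(
            t.feature_type is FeatureType.H and len(t.ligand_atoms) == 3
            for t in templates
        )  # three-carbon tail

    def test_methane_has_no_templates(self):
        topo = make_topology(
            [(1, "C1", "C", "LIG", 1, "A", 0, True)]
            + [(i + 2, f"H{i+1}", "H", "LIG", 1, "A", 0, True) for i in range(4)],
            bonds=[(1, i + 2) for i in range(4)],
        )
        assert perceive_features(topo, "resname LIG") == []

    def test_empty_ligand_selection_raises(self):
        traj = _toy_topology()
        with pytest.raises(PerceptionError):
            with pytest.warns(UserWarning):
                perceive_features(traj.topology, "resname XXX")


class TestClassifyEnvironment:
    def test_partner_classes(self):
        traj = _toy_topology()
        partners = {
            p.label.split(".")[0]: p
            for p in classify_environment(traj.topology, "resname LIG")
        }
        assert partners["MN501"].partner_class == "metal"
        assert partners["OH503"].partner_class == "hydroxide"
        assert partners["SER137"].partner_class == "protein"
        # guanidinium perceived as one positive group of 4 heavy atoms
        assert len(partners["ARG21"].pos_groups[0]) == 4
        # carboxylates as one negative group of the two oxygens
        assert len(partners["ASP183"].neg_groups[0]) == 2
        assert partners["OH503"].neg_groups  # hydroxide counts as negative

    def test_water_class(self):
        topo = make_topology(
            [
                (1, "O", "O", "HOH", 1, "A", 0, False),
                (2, "H1", "H", "HOH", 1, "A", 0, False),
                (3, "H2", "H", "HOH", 1, "A", 0, False),
                (4, "C1", "C", "LIG", 2, "A", 0, True),
            ],
            bonds=[(1, 2), (1, 3)],
        )
        (water,) = classify_environment(topo, "resname LIG")
        assert water.partner_class == "water"


def _hbond_pair(distance, angle_deg):
    """Ligand hydroxyl donating to a backbone-like carbonyl oxygen."""
    topo = make_topology(
        [
            (1, "CA", "C", "GLY", 1, "A", 0, False),
            (2, "C", "C", "GLY", 1, "A", 0, False),
            (3, "O", "O", "GLY", 1, "A", 0, False),
            (4, "C1", "C", "LIG", 2, "A", 0, True),
            (5, "O1", "O", "LIG", 2, "A", 0, True),
            (6, "H1", "H", "LIG", 2, "A", 0, True),
        ],
        bonds=[(1, 2), (2, 3), (4, 5), (5, 6)],
    )
    donor = np.array([0.0, 0.0, 0.0])
    acceptor = np.array([distance, 0.0, 0.0])
    # H at 0.98 Å from donor, placed so the D-H...A angle equals angle_deg
    theta = np.radians(180.0 - angle_deg)
    h = donor + 0.98 * np.array([np.cos(theta), np.sin(theta), 0.0])
    coords = np.array(
        [
            acceptor + [1.2, 1.2, 0.0],
            acceptor + [1.2, 0.0, 0.0],
            acceptor,
            donor + [-1.4, 0.0, 0.0],
            donor,
            h,
        ]
    )
    return topo, Frame(0, coords)


class TestDetection:
    def setup_method(self):
        self.criteria = InteractionCriteria()

    def _detect(self, topo, frame, **kw):
        templates = perceive_features(topo, "resname LIG")
        partners = classify_environment(topo, "resname LIG")
        return detect_frame_interactions(
            topo, frame, templates, partners, self.criteria, **kw
        )

    def test_good_hbond_detected(self):
        topo, frame = _hbond_pair(2.9, 165.0)
        events = [
            e
            for e in self._detect(topo, frame)
            if e.template.feature_type is FeatureType.HBD
        ]
        assert len(events) == 1
        assert events[0].distance == pytest.approx(2.9)

    @pytest.mark.parametrize(
        "distance,angle", [(4.2, 165.0), (2.9, 100.0), (2.0, 165.0)]
    )
    def test_bad_geometry_rejected(self, distance, angle):
        topo, frame = _hbond_pair(distance, angle)
        events = [
            e
            for e in self._detect(topo, frame)
            if e.template.feature_type is FeatureType.HBD
        ]
        assert events == []

    def test_rigid_motion_invariance(self, random_coords_rng):
        topo, frame = _hbond_pair(2.9, 165.0)
        q = random_coords_rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        moved = Frame(0, frame.coords @ rot.T + np.array([4.0, -7.0, 2.0]))
        a = self._detect(topo, frame)
        b = self._detect(topo, moved)
        assert [(e.template.key, e.partner.key) for e in a] == [
            (e.template.key, e.partner.key) for e in b
        ]
        np.testing.assert_allclose(
            [e.distance for e in a], [e.distance for e in b], atol=1e-6
        )

    def test_reordering_symmetry(self):
        topo, frame = _hbond_pair(2.9, 165.0)
        rev_atoms = list(reversed(topo.atoms))
        rev_topo = Topology(rev_atoms, topo.bonds)
        rev_frame = Frame(0, frame.coords[::-1].copy())

        def keyset(topo_, frame_):
            evs = self._detect(topo_, frame_)
            return {
                (
                    e.template.feature_type.value,
                    tuple(
                        topo_.atom(s).name for s in e.template.ligand_atoms
                    ),
                    e.partner.key,
                    round(e.distance, 6),
                )
                for e in evs
            }

        assert keyset(topo, frame) == keyset(rev_topo, rev_frame)

    def test_neighbor_list_equals_brute_force(self):
        """KD-tree prescreened detection is exactly the all-pairs scan."""
        spec = ToySpec(
            n_frames=1, schedules=[hbond_schedule(1, [0])], seed=5
        )
        traj, _ = generate_toy_trajectory(spec)
        topo = traj.topology
        templates = perceive_features(topo, "resname LIG")
        partners = classify_environment(topo, "resname LIG")
        rng = np.random.default_rng(123)
        for _ in range(25):
            frame = Frame(0, rng.uniform(-12, 12, size=(len(topo), 3)))
            fast = detect_frame_interactions(
                topo, frame, templates, partners, self.criteria,
                neighbor_list=True,
            )
            slow = detect_frame_interactions(
                topo, frame, templates, partners, self.criteria,
                neighbor_list=False,
            )
            key = lambda e: (e.template.key, e.partner.key, e.distance)
            assert sorted(map(key, fast)) == sorted(map(key, slow))

    def test_water_excluded_by_default(self):
        topo = make_topology(
            [
                (1, "O", "O", "HOH", 1, "A", 0, False),
                (2, "H1", "H", "HOH", 1, "A", 0, False),
                (3, "H2", "H", "HOH", 1, "A", 0, False),
                (4, "C1", "C", "LIG", 2, "A", 0, True),
                (5, "O1", "O", "LIG", 2, "A", 0, True),
                (6, "H1", "H", "LIG", 2, "A", 0, True),
            ],
            bonds=[(1, 2), (1, 3), (4, 5), (5, 6)],
        )
        coords = np.array(
            [
                [2.9, 0, 0], [3.3, 0.9, 0], [3.3, -0.9, 0],
                [-1.4, 0, 0], [0, 0, 0], [0.98, 0, 0],
            ]
        )
        frame = Frame(0, coords)
        templates = perceive_features(topo, "resname LIG")
        partners = classify_environment(topo, "resname LIG")
        dry = detect_frame_interactions(
            topo, frame, templates, partners, self.criteria
        )
        wet = detect_frame_interactions(
            topo, frame, templates, partners, self.criteria, include_water=True
        )
        assert dry == []
        assert any(
            e.template.feature_type is FeatureType.HBD for e in wet
        )


class TestCriteriaConfig:
    def test_roundtrip_file(self, tmp_path):
        p = tmp_path / "crit.cfg"
        p.write_text("# comment\nhbond_dist_max = 4.0\nionic_dist_max=6.0\n")
        c = InteractionCriteria.from_file(p)
        assert c.hbond_dist_max == 4.0
        assert c.ionic_dist_max == 6.0
        assert c.hbond_dist_min == 2.5  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "crit.cfg"
        p.write_text("bogus = 1.0\n")
        with pytest.raises(ValueError, match="unknown"):
            InteractionCriteria.from_file(p)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            InteractionCriteria(hbond_dist_min=4.0, hbond_dist_max=3.0)
        with pytest.raises(ValueError):
            InteractionCriteria(ionic_dist_max=-1.0)
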