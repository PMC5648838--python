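import numpy as np
import pytest

from dynophore.elements import vdw_radius
from dynophore.percept import FeatureType
from dynophore.synthdata import (
    InteractionSchedule,
    ToySpec,
    generate_toy_trajectory,
)
from dynophore.trajio import AtomRecord, Frame, Topology, Trajectory


def make_topology(rows, bonds=()):
    """Build a Topology from (serial, name, element, resname, resnum,
    chain, charge, is_ligand) rows."""
    atoms = [
        AtomRecord(
            serial=s,
            name=n,
            element=e,
            residue_name=rn,
            residue_number=ri,
            chain_id=ch,
            formal_charge=fc,
            is_ligand=lig,
            vdw_radius=vdw_radius(e),
        )
        for (s, n, e, rn, ri, ch, fc, lig) in rows
    ]
    return Topology(atoms, {frozenset(b) for b in bonds})


def make_trajectory(topology, coord_stack):
    return Trajectory(
        topology, [Frame(i, c) for i, c in enumerate(coord_stack)]
    )


def hbond_schedule(n_frames, active, group="hydroxyl", partner="GLY10",
                   on=2.9, off=6.0):
    return InteractionSchedule(
        FeatureType.HBD, group, partner, frozenset(active), on, off
    )


@pytest.fixture
def simple_hbond_traj():
    """20-frame toy system, one hydroxyl H-bond active in frames 0-7."""
    spec = ToySpec(
        n_frames=20, schedules=[hbond_schedule(20, range(8))], seed=11
    )
    traj, truth = generate_toy_trajectory(spec)
    return traj, truth


@pytest.fixture
def random_coords_rng():
    return np.random.default_rng(20240917)
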