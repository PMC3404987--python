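import numpy as np
import pytest
from hypothesis import settings

from dmsopore import synthetic as syn
from dmsopore.model_io import (
    AtomRole,
    BilayerFrame,
    MoleculeKind,
    Topology,
    Trajectory,
)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def point_dopc_frame(xy_upper, xy_lower, box, z_upper=6.0, z_lower=2.0,
                     time=0.0):
    """Frame of single-atom DOPC 'molecules' (phosphate markers only), one
    plane per leaflet; handy for leaflet, P-P and C(r) constructions."""
    xy_upper = np.atleast_2d(xy_upper)
    xy_lower = np.atleast_2d(xy_lower)
    n = len(xy_upper) + len(xy_lower)
    pos = np.zeros((n, 3))
    pos[:len(xy_upper), :2] = xy_upper
    pos[:len(xy_upper), 2] = z_upper
    pos[len(xy_upper):, :2] = xy_lower
    pos[len(xy_upper):, 2] = z_lower
    topo = Topology(
        atom_ids=np.arange(n), mol_ids=np.arange(n),
        mol_kinds=np.full(n, int(MoleculeKind.DOPC)),
        atom_names=np.full(n, "P", dtype="<U5"),
        roles=np.full(n, int(AtomRole.PHOSPHATE_MARKER)),
        tail_chain=np.full(n, -1), tail_pos=np.full(n, -1),
        masses=np.full(n, 30.974))
    return BilayerFrame(topo, np.mod(pos, box), np.asarray(box, float), time)


def chain_frame(chains, box, with_phosphate=True, time=0.0):
    """Frame of DOPC molecules each carrying one tail of given coordinates.

    ``chains``: iterable of (n_carbons, 3) arrays.  A phosphate marker is
    placed 0.2 nm above each chain start so roles stay legal.
    """
    b = syn._Builder()
    for chain in chains:
        chain = np.asarray(chain, float)
        b.new_molecule(MoleculeKind.DOPC)
        if with_phosphate:
            b.atom("P", AtomRole.PHOSPHATE_MARKER,
                   chain[0] + [0, 0, 0.2], 30.974)
        for k, p in enumerate(chain):
            b.atom(f"C{k + 1}A", AtomRole.TAIL_CARBON, p, 14.027,
                   tchain=0, tpos=k + 1)
    return b.frame(np.asarray(box, float), time)


def straight_chain(origin, director, n_carbons=18, spacing=0.125):
    """Perfectly collinear carbons along ``director`` (exact tilt axis)."""
    u = np.asarray(director, float)
    u = u / np.linalg.norm(u)
    return np.asarray(origin, float) + spacing * np.arange(n_carbons)[:, None] * u


def zigzag_chain(origin, director, n_carbons=18, azimuth=0.0):
    """Ideal tetrahedral zigzag along ``director`` starting at ``origin``."""
    u = np.asarray(director, float)
    u = u / np.linalg.norm(u)
    pos = syn._build_chains(u[None, :], np.array([azimuth]),
                            np.zeros((1, n_carbons, 2)), 0.0)[0]
    return np.asarray(origin, float) + pos[:, :]


@pytest.fixture(scope="session")
def lipid_traj():
    """Solvent-free bilayer at the DMSO-free structural targets, 25 frames."""
    spec = syn.GeneratorSpec(n_solvent=0, seed=11)
    return syn.generate_trajectory(spec, n_frames=25)


@pytest.fixture(scope="session")
def solvated_traj():
    """Small solvated bilayer with 10 mol% DMSO in the solvent, 6 frames."""
    spec = syn.GeneratorSpec(n_dopc=64, n_solvent=2000,
                             dmso_solvent_mol_fraction=0.10,
                             box_xy=4.75, seed=7)
    return syn.generate_trajectory(spec, n_frames=6)


def small_pore_spec(seed):
    return syn.GeneratorSpec(n_dopc=32, n_solvent=400, box_xy=4.0, seed=seed)


@pytest.fixture(scope="session")
def pore_suite():
    """20 seeded trajectories with per-seed plant plans and ground truth.

    Returns a list of (trajectory, plan_label) with labels
    'none' / 'column' / 'hydrophilic' / 'triple'.
    """
    out = []
    for seed in range(20):
        traj = syn.generate_trajectory(small_pore_spec(seed), n_frames=12)
        if seed < 7:
            label = "none"
        elif seed < 14:
            traj = syn.plant_pore(
                traj, syn.PorePlan("HYDROPHOBIC_COLUMN", radius=0.15,
                                   frames_present=(5, 5)), seed=seed)
            label = "column"
        elif seed < 17:
            traj = syn.plant_pore(
                traj, syn.PorePlan("HYDROPHILIC_PORE", radius=0.15,
                                   n_lining_headgroups=8,
                                   frames_present=(0, 11)), seed=seed)
            label = "hydrophilic"
        else:
            for j, c in enumerate((1.0, 2.0, 3.0)):
                traj = syn.plant_pore(
                    traj, syn.PorePlan("HYDROPHOBIC_COLUMN", radius=0.12,
                                       frames_present=(4, 6),
                                       center_xy=(c, c)), seed=100 * seed + j)
            label = "triple"
        out.append((traj, label))
    return out
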