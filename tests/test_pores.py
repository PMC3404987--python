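import numpy as np
import pytest

from dmsopore import pores as po
from dmsopore import synthetic as syn
from dmsopore.model_io import AtomRole, BilayerFrame, Trajectory
from dmsopore.pores import PoreConfig


def brute_force_partition(frame, config=PoreConfig()):
    """Independent oracle: O(N^2) in-plane minimum-image distances over slab
    water oxygens + BFS connected components via networkx."""
    import networkx as nx

    bounds = po._slab_bounds(frame, config)
    if bounds is None:
        return set()
    z_lo, z_hi = bounds
    t = frame.topology
    idx = np.flatnonzero(t.roles == AtomRole.WATER_O)
    z = frame.positions[idx, 2]
    idx = idx[(z >= z_lo) & (z <= z_hi)]
    pos = frame.positions[idx]
    g = nx.Graph()
    g.add_nodes_from(range(len(idx)))
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            d = pos[i] - pos[j]
            d[:2] -= frame.box[:2] * np.round(d[:2] / frame.box[:2])
            if np.dot(d, d) <= config.oo_cutoff ** 2:
                g.add_edge(i, j)
    return {frozenset(int(t.mol_ids[idx[i]]) for i in comp)
            for comp in nx.connected_components(g)}


def detector_partition(frame, config=PoreConfig()):
    return {d.member_water_ids for d in po.detect_defects(frame, config)}


class TestDetector:
    def test_no_slab_water_empty_list(self):
        spec = syn.GeneratorSpec(n_dopc=16, n_solvent=100, box_xy=4.0,
                                 water_core_penetration=0.0, seed=1)
        traj = syn.generate_trajectory(spec, n_frames=1)
        assert po.detect_defects(traj.frames[0]) == []

    def test_two_isolated_waters_two_nonspanning_defects(self):
        spec = syn.GeneratorSpec(n_dopc=16, n_solvent=60, box_xy=4.0,
                                 water_core_penetration=0.0, seed=2)
        traj = syn.generate_trajectory(spec, n_frames=1)
        f = traj.frames[0]
        t = f.topology
        ow = np.flatnonzero(t.roles == AtomRole.WATER_O)
        pos = f.positions.copy()
        # drop two waters 2 nm apart at the bilayer centre
        for o_i, xy in zip(ow[:2], ([0.5, 0.5], [2.5, 2.5])):
            mol = t.mol_ids[o_i]
            sel = np.flatnonzero(t.mol_ids == mol)
            shift = np.array([xy[0], xy[1], f.box[2] / 2]) - pos[o_i]
            pos[sel] += shift
        defects = po.detect_defects(BilayerFrame(t, np.mod(pos, f.box),
                                                 f.box))
        assert len(defects) == 2
        assert not any(d.spans_slab for d in defects)

    def test_collapsed_bilayer_returns_empty(self):
        spec = syn.GeneratorSpec(n_dopc=16, n_solvent=60, box_xy=4.0, seed=3)
        traj = syn.generate_trajectory(spec, n_frames=1)
        f = traj.frames[0]
        t = f.topology
        pos = f.positions.copy()
        p = t.roles == AtomRole.PHOSPHATE_MARKER
        pos[p, 2] = 7.0  # all phosphates on one plane
        assert po.detect_defects(BilayerFrame(t, pos, f.box)) == []

    def test_permutation_invariance(self):
        spec = syn.GeneratorSpec(n_dopc=16, n_solvent=300, box_xy=4.0,
                                 water_core_penetration=0.3, seed=4)
        f = syn.generate_trajectory(spec, n_frames=1).frames[0]
        sizes = sorted(len(d.member_water_ids)
                       for d in po.detect_defects(f))
        t = f.topology
        rng = np.random.default_rng(0)
        perm = rng.permutation(t.n_atoms)
        from dmsopore.model_io import Topology
        t2 = Topology(t.atom_ids[perm], t.mol_ids[perm], t.mol_kinds[perm],
                      t.atom_names[perm], t.roles[perm], t.tail_chain[perm],
                      t.tail_pos[perm], t.masses[perm])
        f2 = BilayerFrame(t2, f.positions[perm], f.box)
        sizes2 = sorted(len(d.member_water_ids)
                        for d in po.detect_defects(f2))
        assert sizes == sizes2

    def test_cutoff_monotonicity(self):
        spec = syn.GeneratorSpec(n_dopc=16, n_solvent=300, box_xy=4.0,
                                 water_core_penetration=0.4, seed=5)
        f = syn.generate_trajectory(spec, n_frames=1).frames[0]
        small = detector_partition(f, PoreConfig(oo_cutoff=0.30))
        large = detector_partition(f, PoreConfig(oo_cutoff=0.45))
        # every small-cutoff cluster is contained in one large-cutoff cluster
        for s in small:
            assert any(s <= l for l in large)


@pytest.fixture(scope="module")
def base_traj():
    return syn.generate_trajectory(
        syn.GeneratorSpec(n_dopc=32, n_solvent=400, box_xy=4.0, seed=21),
        n_frames=12)


class TestTracking:
    def test_single_frame_column_lifetime(self, base_traj):
        traj = syn.plant_pore(base_traj,
                              syn.PorePlan("HYDROPHOBIC_COLUMN", radius=0.15,
                                           frames_present=(5, 5)), seed=1)
        events = po.track_defects(traj)
        assert len(events) == 1
        ev = events[0]
        assert (ev.first_frame, ev.last_frame) == (5, 5)
        assert ev.lifetime == pytest.approx(traj.frame_interval)
        assert ev.pore_class == "TRANSIENT_HYDROPHOBIC"

    def test_multiframe_column_links_into_one_event(self, base_traj):
        traj = syn.plant_pore(base_traj,
                              syn.PorePlan("HYDROPHOBIC_COLUMN", radius=0.15,
                                           frames_present=(3, 9)), seed=2)
        events = po.track_defects(traj)
        assert len(events) == 1
        assert (events[0].first_frame, events[0].last_frame) == (3, 9)
        assert events[0].n_frames == 7

    def test_disjoint_columns_two_events(self, base_traj):
        traj = syn.plant_pore(base_traj,
                              syn.PorePlan("HYDROPHOBIC_COLUMN", radius=0.12,
                                           frames_present=(4, 6),
                                           center_xy=(1.0, 1.0)), seed=3)
        traj = syn.plant_pore(traj,
                              syn.PorePlan("HYDROPHOBIC_COLUMN", radius=0.12,
                                           frames_present=(4, 6),
                                           center_xy=(3.0, 3.0)), seed=4)
        events = po.track_defects(traj)
        assert len(events) == 2
        ids0 = set.union(*[set(d.member_water_ids)
                           for d in events[0].defect_track])
        ids1 = set.union(*[set(d.member_water_ids)
                           for d in events[1].defect_track])
        assert not ids0 & ids1

    def test_long_lived_bare_column_indeterminate(self, base_traj):
        traj = syn.plant_pore(base_traj,
                              syn.PorePlan("HYDROPHOBIC_COLUMN", radius=0.15,
                                           frames_present=(0, 11)), seed=5)
        events = po.track_defects(traj)
        assert len(events) == 1
        assert events[0].pore_class == "INDETERMINATE"

    def test_hydrophilic_pore_classified_stable(self, base_traj):
        traj = syn.plant_pore(base_traj,
                              syn.PorePlan("HYDROPHILIC_PORE", radius=0.15,
                                           n_lining_headgroups=8,
                                           frames_present=(0, 11)), seed=6)
        events = po.track_defects(traj)
        assert len(events) == 1
        assert events[0].pore_class == "STABLE_HYDROPHILIC"
        assert max(d.lining_headgroup_count
                   for d in events[0].defect_track) >= 6


class TestRegimeSuite:
    """The 20-trajectory planted-defect suite: detector oracle equality,
    perfect recall/precision, and regime labels matching the plant plans."""

    EXPECTED_REGIME = {"none": "I", "column": "I", "hydrophilic": "II",
                       "triple": "III"}

    def test_detector_equals_bruteforce_oracle(self, pore_suite):
        checked = 0
        for traj, _label in pore_suite[::4]:  # every 4th: 5 trajectories
            for frame in traj:
                assert detector_partition(frame) == \
                    brute_force_partition(frame)
                checked += 1
        assert checked >= 50

    def test_planted_recall_and_precision(self, pore_suite):
        for traj, label in pore_suite:
            planted = traj.metadata.get("planted", [])
            expected_per_frame = np.zeros(traj.n_frames, dtype=int)
            for rec in planted:
                a, b = rec["frames"]
                expected_per_frame[a:b + 1] += 1
            for k, frame in enumerate(traj):
                spanning = [d for d in po.detect_defects(frame)
                            if d.spans_slab]
                assert len(spanning) == expected_per_frame[k], \
                    f"{label} seed traj frame {k}"

    def test_regimes_match_plant_plans(self, pore_suite):
        for traj, label in pore_suite:
            report = po.classify_regime(traj)
            assert report.regime == self.EXPECTED_REGIME[label], label
            if label == "hydrophilic":
                assert report.n_stable >= 1 and report.bilayer_intact
            if label == "triple":
                assert report.max_simultaneous_spanning >= 3

    def test_short_trajectory_undetermined(self):
        traj = syn.generate_trajectory(
            syn.GeneratorSpec(n_dopc=16, n_solvent=100, box_xy=4.0, seed=33),
            n_frames=3)
        assert po.classify_regime(traj).regime == "UNDETERMINED"

    def test_evidence_cites_thresholds(self, pore_suite):
        traj, _ = pore_suite[0]
        report = po.classify_regime(traj)
        assert any("oo_cutoff" in line for line in report.evidence)
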