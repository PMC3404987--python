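"""Transmembrane water defect detection, tracking and regime classification.

A *defect* is a cluster of water oxygens inside the hydrophobic slab
(between the leaflet mean phosphate planes, shrunk by a margin), built by
single-linkage at the first-hydration-shell O-O cutoff with in-plane
periodic minimum image.  A defect *spans* the slab when its members reach
within one cutoff of both slab faces.  Spanning defects in consecutive
frames sharing members form a :class:`PoreEvent`; events are classed
transient-hydrophobic vs stable-hydrophilic from their lifetime and the
count of lipid headgroup / Chol hydroxyl atoms lining the column.  A
trajectory is labelled with a concentration regime:

I   - intact bilayer, no stable pore (at most transient columns);
II  - intact bilayer with at least one stable hydrophilic pore;
III - bilayer not intact in some frame, or >= 3 simultaneous spanning
      defects (multiple-pore destruction).

The phenomenological "stable" vs "very transient" split is qualitative; the
numeric thresholds here are pre-registered configuration constants,
reported in every output.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model_io import AtomRole, Trajectory, assign_leaflets

__all__ = [
    "PoreConfig",
    "WaterDefect",
    "PoreEvent",
    "RegimeReport",
    "detect_defects",
    "track_defects",
    "classify_pore",
    "classify_regime",
]


@dataclasses.dataclass(frozen=True)
class PoreConfig:
    """Pre-registered detection/classification constants."""

    oo_cutoff: float = 0.35  # nm, first hydration shell O-O distance
    slab_margin: float = 0.3  # nm shaved off each phosphate plane
    stability_frames: int = 10  # lifetime threshold (frames)
    lining_threshold: int = 6  # headgroup atoms for "hydrophilic"
    lining_radius: float = 0.6  # nm from the column axis
    multiple_pore_threshold: int = 3  # simultaneous spanning defects => III
    include_dmso_members: bool = False  # DMSO may join defect membership

    def as_header(self) -> str:
        return ("oo_cutoff_nm=%.3f slab_margin_nm=%.3f stability_frames=%d "
                "lining_threshold=%d lining_radius_nm=%.3f "
                "multiple_pore_threshold=%d include_dmso_members=%s"
                % (self.oo_cutoff, self.slab_margin, self.stability_frames,
                   self.lining_threshold, self.lining_radius,
                   self.multiple_pore_threshold, self.include_dmso_members))


@dataclasses.dataclass
class WaterDefect:
    frame_index: int
    member_water_ids: frozenset  # molecule ids
    spans_slab: bool
    axis_xy: np.ndarray  # in-plane centroid (periodic mean), nm
    max_radius: float  # nm
    lining_headgroup_count: int


@dataclasses.dataclass
class PoreEvent:
    defect_track: list  # WaterDefect per frame, consecutive
    first_frame: int
    last_frame: int
    lifetime: float  # ps
    pore_class: str = "UNCLASSIFIED"

    @property
    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1


@dataclasses.dataclass
class RegimeReport:
    regime: str  # "I" | "II" | "III" | "UNDETERMINED"
    n_transient: int
    n_stable: int
    max_simultaneous_spanning: int
    bilayer_intact: bool
    evidence: list
    config: PoreConfig


def _slab_bounds(frame, config):
    """(z_lo, z_hi) of the hydrophobic slab, or None when the bilayer is
    collapsed."""
    la = assign_leaflets(frame)
    if not la.intact:
        return None
    t = frame.topology
    p = t.roles == AtomRole.PHOSPHATE_MARKER
    z = frame.positions[p, 2]
    upper = z > la.midplane_z
    if not (np.any(upper) and np.any(~upper)):
        return None
    z_lo = float(np.mean(z[~upper])) + config.slab_margin
    z_hi = float(np.mean(z[upper])) - config.slab_margin
    if z_hi - z_lo <= 0:
        return None
    return z_lo, z_hi


def _periodic_centroid(xy, box_xy):
    """Centroid of in-plane points under periodicity (circular mean)."""
    out = np.empty(2)
    for ax in range(2):
        ang = xy[:, ax] / box_xy[ax] * 2 * np.pi
        m = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        out[ax] = (m % (2 * np.pi)) / (2 * np.pi) * box_xy[ax]
    return out


def detect_defects(frame, config: PoreConfig = PoreConfig()) -> list:
    """Cluster slab waters into defects (single linkage, in-plane periodic).

    Returns an empty list for a collapsed bilayer (no defined slab); the
    caller sees that through :func:`classify_regime`'s intact check.
    """
    bounds = _slab_bounds(frame, config)
    if bounds is None:
        return []
    z_lo, z_hi = bounds
    t = frame.topology
    member_roles = t.roles == AtomRole.WATER_O
    if config.include_dmso_members:
        member_roles |= t.roles == AtomRole.DMSO_S
    idx = np.flatnonzero(member_roles)
    z = frame.positions[idx, 2]
    inside = (z >= z_lo) & (z <= z_hi)
    idx = idx[inside]
    if idx.size == 0:
        return []
    pos = frame.positions[idx]
    box = frame.box

    # kd-tree with full toroidal wrap; z wrap is inert because slab waters
    # sit far from the z faces
    tree = cKDTree(np.mod(pos, box), boxsize=box)
    pairs = np.array(list(tree.query_pairs(config.oo_cutoff)), dtype=int)
    n = idx.size
    if pairs.size:
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)

    head = (t.roles == AtomRole.PHOSPHATE_MARKER) | \
        (t.roles == AtomRole.CHOL_HYDROXYL_O)
    head_idx = np.flatnonzero(head)
    hz = frame.positions[head_idx, 2]
    head_idx = head_idx[(hz >= z_lo) & (hz <= z_hi)]
    head_xy = frame.positions[head_idx, :2]

    defects = []
    for lab in range(n_comp):
        sel = labels == lab
        members = idx[sel]
        mol_ids = frozenset(int(m) for m in t.mol_ids[members])
        zs = pos[sel, 2]
        spans = bool(zs.min() <= z_lo + config.oo_cutoff
                     and zs.max() >= z_hi - config.oo_cutoff)
        axis = _periodic_centroid(pos[sel, :2], box[:2])
        d = pos[sel, :2] - axis
        d -= box[:2] * np.round(d / box[:2])
        max_radius = float(np.hypot(d[:, 0], d[:, 1]).max())
        if head_idx.size:
            dh = head_xy - axis
            dh -= box[:2] * np.round(dh / box[:2])
            lining = int(np.sum(np.hypot(dh[:, 0], dh[:, 1])
                                <= config.lining_radius))
        else:
            lining = 0
        defects.append(WaterDefect(
            frame_index=-1, member_water_ids=mol_ids, spans_slab=spans,
            axis_xy=axis, max_radius=max_radius,
            lining_headgroup_count=lining))
    return defects


def track_defects(traj: Trajectory,
                  config: PoreConfig = PoreConfig()) -> list:
    """Link spanning defects across consecutive frames into PoreEvents.

    Defects in frames k and k+1 link when they share at least one member
    water; maximal linked chains (connected components over the time-link
    graph) become events, classified by :func:`classify_pore`.
    """
    per_frame = []
    for k, frame in enumerate(traj.frames):
        found = detect_defects(frame, config)
        for d in found:
            d.frame_index = k
        per_frame.append([d for d in found if d.spans_slab])

    nodes = [d for frame_defects in per_frame for d in frame_defects]
    if not nodes:
        return []
    node_id = {id(d): i for i, d in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for k in range(len(per_frame) - 1):
        for a in per_frame[k]:
            for b in per_frame[k + 1]:
                if a.member_water_ids & b.member_water_ids:
                    union(node_id[id(a)], node_id[id(b)])

    groups: dict = {}
    for d in nodes:
        groups.setdefault(find(node_id[id(d)]), []).append(d)
    events = []
    for members in groups.values():
        members.sort(key=lambda d: d.frame_index)
        first = members[0].frame_index
        last = members[-1].frame_index
        ev = PoreEvent(defect_track=members, first_frame=first,
                       last_frame=last,
                       lifetime=(last - first + 1) * traj.frame_interval)
        ev.pore_class = classify_pore(ev, n_frames_total=traj.n_frames,
                                      config=config)
        events.append(ev)
    events.sort(key=lambda e: (e.first_frame, e.last_frame))
    return events


def classify_pore(event: PoreEvent, n_frames_total: int | None = None,
                  config: PoreConfig = PoreConfig()) -> str:
    """TRANSIENT_HYDROPHOBIC / STABLE_HYDROPHILIC / INDETERMINATE.

    Stable: lifetime >= the stability threshold, or persistence to the end
    of the trajectory.  Hydrophilic: the lining criterion (>= threshold
    headgroup atoms within the lining radius) holds in at least half the
    event's frames.
    """
    n_lined = sum(d.lining_headgroup_count >= config.lining_threshold
                  for d in event.defect_track)
    lined = n_lined * 2 >= len(event.defect_track)
    stable = event.n_frames >= config.stability_frames
    if n_frames_total is not None and event.last_frame == n_frames_total - 1:
        stable = True
    if stable and lined:
        return "STABLE_HYDROPHILIC"
    if not stable and not lined:
        return "TRANSIENT_HYDROPHOBIC"
    return "INDETERMINATE"


def classify_regime(traj: Trajectory,
                    config: PoreConfig = PoreConfig()) -> RegimeReport:
    """Label a trajectory I / II / III (or UNDETERMINED) with evidence."""
    evidence = [f"thresholds: {config.as_header()}"]
    intact = True
    max_span = 0
    for k, frame in enumerate(traj.frames):
        if _slab_bounds(frame, config) is None:
            intact = False
            evidence.append(f"frame {k}: bilayer not intact (no defined slab)")
    events = track_defects(traj, config)
    span_per_frame = np.zeros(traj.n_frames, dtype=int)
    for ev in events:
        for d in ev.defect_track:
            span_per_frame[d.frame_index] += 1
    max_span = int(span_per_frame.max()) if traj.n_frames else 0
    n_stable = sum(ev.pore_class == "STABLE_HYDROPHILIC" for ev in events)
    n_transient = sum(ev.pore_class == "TRANSIENT_HYDROPHOBIC"
                      for ev in events)

    if not intact or max_span >= config.multiple_pore_threshold:
        regime = "III"
        if max_span >= config.multiple_pore_threshold:
            evidence.append(
                f"{max_span} simultaneous spanning defects "
                f"(threshold {config.multiple_pore_threshold})")
    elif traj.n_frames < config.stability_frames:
        regime = "UNDETERMINED"
        evidence.append(
            f"trajectory of {traj.n_frames} frames is shorter than the "
            f"stability threshold ({config.stability_frames}); cannot tell "
            "stable pores from transient ones")
    elif n_stable >= 1:
        regime = "II"
        for ev in events:
            if ev.pore_class == "STABLE_HYDROPHILIC":
                evidence.append(
                    f"stable hydrophilic pore frames "
                    f"{ev.first_frame}-{ev.last_frame} "
                    f"(lifetime {ev.lifetime:g} ps)")
    else:
        regime = "I"
        evidence.append(
            f"intact bilayer; {n_transient} transient defect(s), "
            "no stable pore")
    return RegimeReport(regime=regime, n_transient=n_transient,
                        n_stable=n_stable,
                        max_simultaneous_spanning=max_span,
                        bilayer_intact=intact, evidence=evidence,
                        config=config)
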