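"""Chain order, tilt, lateral organization and dipole orientation.

* ``scd_profile`` - deuterium order parameter S_CD = <(3 cos^2 t - 1)/2> of
  the C-H(D) bond vs the bilayer normal, reported as -S_CD per carbon and
  averaged over all CD segments.  For united-atom chains the two H
  directions are reconstructed assuming ideal tetrahedral geometry.
* ``tilt_angles`` - mean acyl-chain (first -> last tail carbon) and Chol-axis
  (hydroxyl O -> last ring-axis carbon) angles vs each molecule's outward
  leaflet normal, folded to [0, 90] degrees.
* ``lateral_correlation`` - in-plane pair density correlation C(r) of DOPC
  centers of mass, per leaflet, normalized to 1 for a homogeneous fluid.
* ``dipole_orientation_profile`` - mean angle of the DMSO O->S (or water
  dipole) vector vs the outward normal of the nearer leaflet, binned in Z'.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .model_io import (
    AtomRole,
    MoleculeKind,
    Trajectory,
    assign_leaflets,
    minimum_image,
)
from .profiles import MembraneScaling, membrane_scaling, ScalingError

__all__ = [
    "OrderProfile",
    "TiltSummary",
    "LateralCorrelation",
    "OrientationProfile",
    "scd_profile",
    "tilt_angles",
    "lateral_correlation",
    "dipole_orientation_profile",
]

_COS_B = 1.0 / math.sqrt(3.0)  # half tetrahedral H-C-H angle
_SIN_B = math.sqrt(2.0 / 3.0)


@dataclasses.dataclass
class OrderProfile:
    """-S_CD per (chain, carbon) plus the segment-average."""

    chains: np.ndarray  # chain index per entry
    carbons: np.ndarray  # carbon position per entry
    minus_scd: np.ndarray
    mean_minus_scd: float


@dataclasses.dataclass
class TiltSummary:
    tail_tilt_deg: float
    chol_tilt_deg: float  # NaN when no Chol present


@dataclasses.dataclass
class LateralCorrelation:
    r_bins: np.ndarray  # bin centers, nm
    r_edges: np.ndarray
    c_value: np.ndarray
    pair_counts: np.ndarray  # ordered pairs per bin (summed over frames/leaflets)
    reference_density: float  # molecules nm^-2
    n_reference: int


@dataclasses.dataclass
class OrientationProfile:
    species: str
    bin_centers: np.ndarray  # Z'
    mean_angle_deg: np.ndarray  # NaN where empty
    n_samples: np.ndarray


# ---------------------------------------------------------------------------

def _chain_groups(traj):
    """(mol_id, chain) -> atom indices sorted by carbon position, DOPC only."""
    t = traj.topology
    mask = (t.roles == AtomRole.TAIL_CARBON) & (t.mol_kinds == MoleculeKind.DOPC)
    idx = np.flatnonzero(mask)
    groups: dict = {}
    for i in idx:
        groups.setdefault((int(t.mol_ids[i]), int(t.tail_chain[i])), []).append(i)
    out = {}
    for key, members in groups.items():
        members = sorted(members, key=lambda i: int(t.tail_pos[i]))
        out[key] = np.array(members)
    return out


def _unwrapped_chain(frame, members):
    """Chain coordinates rebuilt from minimum-image bond vectors (wrapping-
    safe for intramolecular geometry)."""
    pos = frame.positions[members]
    bonds = minimum_image(np.diff(pos, axis=0), frame.box)
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(bonds, axis=0)
    return out


def reconstructed_ch_cos2(chain_pos) -> np.ndarray:
    """cos^2 of the two tetrahedrally reconstructed C-H directions vs z for
    every interior carbon of one chain; shape (n_interior, 2)."""
    b = np.diff(chain_pos, axis=0)
    a = b[1:] + b[:-1]
    d = 0.5 * (b[:-1] - b[1:])
    a_hat = a / np.linalg.norm(a, axis=-1, keepdims=True)
    d_perp = d - np.sum(d * a_hat, axis=-1, keepdims=True) * a_hat
    nrm = np.linalg.norm(d_perp, axis=-1, keepdims=True)
    d_hat = np.divide(d_perp, nrm, out=np.zeros_like(d_perp), where=nrm > 1e-12)
    n_hat = np.cross(a_hat, d_hat)
    c1 = _COS_B * d_hat[:, 2] + _SIN_B * n_hat[:, 2]
    c2 = _COS_B * d_hat[:, 2] - _SIN_B * n_hat[:, 2]
    return np.stack([c1 * c1, c2 * c2], axis=1)


def scd_profile(traj: Trajectory) -> OrderProfile:
    """-S_CD per tail carbon, averaged over molecules, frames and the two
    reconstructed C-H vectors; terminal carbons are excluded."""
    groups = _chain_groups(traj)
    if not groups:
        raise ValueError("no DOPC tail carbons with tail indices present")
    acc: dict = {}
    for frame in traj.frames:
        for (mol, chain), members in groups.items():
            if len(members) < 3:
                warnings.warn(f"chain {(mol, chain)} shorter than 3 carbons; "
                              "skipped", stacklevel=2)
                continue
            cos2 = reconstructed_ch_cos2(_unwrapped_chain(frame, members))
            scd = 0.5 * (3.0 * cos2.mean(axis=1) - 1.0)
            t = traj.topology
            carbons = t.tail_pos[members][1:-1]
            for c, s in zip(carbons, scd):
                key = (chain, int(c))
                tot, n = acc.get(key, (0.0, 0))
                acc[key] = (tot + s, n + 1)
    keys = sorted(acc)
    chains = np.array([k[0] for k in keys])
    carbons = np.array([k[1] for k in keys])
    minus = np.array([-acc[k][0] / acc[k][1] for k in keys])
    return OrderProfile(chains=chains, carbons=carbons, minus_scd=minus,
                        mean_minus_scd=float(np.mean(minus)))


def _folded_angle_deg(vec, outward_z: float) -> float:
    """Angle of a vector vs the axis outward_z * +z, folded to [0, 90]."""
    c = abs(vec[2] * outward_z) / np.linalg.norm(vec)
    return math.degrees(math.acos(min(c, 1.0)))


def tilt_angles(traj: Trajectory) -> TiltSummary:
    """Mean acyl and Chol tilt vs the outward leaflet normal, degrees."""
    t = traj.topology
    groups = _chain_groups(traj)
    chol_mask = (t.roles == AtomRole.TAIL_CARBON) & \
        (t.mol_kinds == MoleculeKind.CHOL)
    chol_groups: dict = {}
    for i in np.flatnonzero(chol_mask):
        chol_groups.setdefault(int(t.mol_ids[i]), []).append(i)
    oh_of = {int(t.mol_ids[i]): i for i in
             np.flatnonzero(t.roles == AtomRole.CHOL_HYDROXYL_O)}

    tail_angles, chol_angles = [], []
    for frame in traj.frames:
        leaf = assign_leaflets(frame).as_dict()
        for (mol, _chain), members in groups.items():
            side = leaf.get(mol, 0)
            if side == 0 or len(members) < 2:
                continue
            chain_pos = _unwrapped_chain(frame, members)
            tail_angles.append(
                _folded_angle_deg(chain_pos[-1] - chain_pos[0], side))
        for mol, members in chol_groups.items():
            side = leaf.get(mol, 0)
            if side == 0 or mol not in oh_of:
                warnings.warn(f"Chol molecule {mol} lacks axis atoms; skipped",
                              stacklevel=2)
                continue
            members = sorted(members, key=lambda i: int(t.tail_pos[i]))
            top = frame.positions[oh_of[mol]]
            axis = minimum_image(frame.positions[members[-1]] - top, frame.box)
            chol_angles.append(_folded_angle_deg(axis, side))
    if not tail_angles:
        raise ValueError("no assignable acyl chains for tilt analysis")
    chol = float(np.mean(chol_angles)) if chol_angles else float("nan")
    return TiltSummary(tail_tilt_deg=float(np.mean(tail_angles)),
                       chol_tilt_deg=chol)


# ---------------------------------------------------------------------------

def _dopc_centers_of_mass(frame):
    """Per-DOPC center of mass, unwrapped about the phosphate marker."""
    t = frame.topology
    mask = t.mol_kinds == MoleculeKind.DOPC
    mids = np.unique(t.mol_ids[mask])
    coms = np.empty((len(mids), 3))
    for k, mol in enumerate(mids):
        sel = np.flatnonzero(t.mol_ids == mol)
        anchor_candidates = sel[t.roles[sel] == AtomRole.PHOSPHATE_MARKER]
        anchor = anchor_candidates[0] if anchor_candidates.size else sel[0]
        rel = minimum_image(frame.positions[sel] - frame.positions[anchor],
                            frame.box)
        m = t.masses[sel]
        coms[k] = frame.positions[anchor] + (m[:, None] * rel).sum(0) / m.sum()
    return mids, coms


def lateral_correlation(traj: Trajectory, bin_width: float = 0.05,
                        r_max: float | None = None) -> LateralCorrelation:
    """In-plane pair correlation C(r) of DOPC centers of mass.

    Computed per leaflet with in-plane minimum image, pair counts per
    annulus normalized by annulus area x reference density x reference
    count; leaflet and frame curves are count-weighted averages.
    """
    box = traj.frames[0].box
    bound = min(box[0], box[1]) / 2.0
    if r_max is None:
        r_max = bound
    if r_max > bound + 1e-12:
        raise ValueError(f"r_max={r_max} exceeds min(Lx, Ly)/2 = {bound}")
    nbins = int(math.ceil(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)

    pair_counts = np.zeros(nbins)
    norm = np.zeros(nbins)
    dens_acc, dens_n = 0.0, 0
    n_ref_total = 0
    for frame in traj.frames:
        leaf = assign_leaflets(frame).as_dict()
        mids, coms = _dopc_centers_of_mass(frame)
        sides = np.array([leaf.get(int(m), 0) for m in mids])
        for side in (1, -1):
            xy = coms[sides == side][:, :2]
            n = len(xy)
            if n < 2:
                raise ValueError("need >= 2 DOPC per leaflet for C(r)")
            d = xy[:, None, :] - xy[None, :, :]
            d -= box[:2] * np.round(d / box[:2])
            r = np.hypot(d[..., 0], d[..., 1])
            iu = ~np.eye(n, dtype=bool)
            hist, _ = np.histogram(r[iu], bins=edges)
            rho_ref = (n - 1) / frame.area
            pair_counts += hist
            norm += n * rho_ref * areas
            dens_acc += n / frame.area
            dens_n += 1
            n_ref_total += n
    c = np.divide(pair_counts, norm, out=np.zeros(nbins), where=norm > 0)
    return LateralCorrelation(
        r_bins=0.5 * (edges[:-1] + edges[1:]), r_edges=edges, c_value=c,
        pair_counts=pair_counts,
        reference_density=dens_acc / max(dens_n, 1),
        n_reference=n_ref_total)


# ---------------------------------------------------------------------------

_SPECIES_ROLES = {
    "DMSO": (AtomRole.DMSO_O, AtomRole.DMSO_S),
    "WATER": (AtomRole.WATER_O, AtomRole.WATER_H),
}


def _identity_scaling(frame) -> MembraneScaling:
    lz = float(frame.box[2])
    return MembraneScaling(z_mid=lz / 2.0, h_upper=1.0, h_lower=1.0)


def dipole_orientation_profile(traj: Trajectory, species: str,
                               bin_width: float = 0.1,
                               scaling: MembraneScaling | None = None
                               ) -> OrientationProfile:
    """Mean dipole angle vs the outward normal of the nearer leaflet,
    binned by the molecule's Z'.

    DMSO dipole = O -> S vector; water dipole = bisector of the two O->H
    bonds (negative-to-positive convention in both cases).  Without
    phosphates (pure solvent boxes) Z' falls back to z - Lz/2 in nm about
    the box center.
    """
    species = species.upper()
    if species not in _SPECIES_ROLES:
        raise ValueError(f"species must be DMSO or WATER, got {species!r}")
    t = traj.topology
    if scaling is None:
        try:
            scaling = membrane_scaling(traj)
        except ScalingError:
            scaling = _identity_scaling(traj.frames[0])

    if species == "DMSO":
        o_idx = np.flatnonzero(t.roles == AtomRole.DMSO_O)
        s_idx = np.flatnonzero(t.roles == AtomRole.DMSO_S)
        if o_idx.size == 0 or s_idx.size == 0:
            raise ValueError("DMSO O/S roles missing; cannot build dipoles")
        order_o = o_idx[np.argsort(t.mol_ids[o_idx], kind="stable")]
        order_s = s_idx[np.argsort(t.mol_ids[s_idx], kind="stable")]
        if not np.array_equal(t.mol_ids[order_o], t.mol_ids[order_s]):
            raise ValueError("unpaired DMSO O/S atoms")
    else:
        o_idx = np.flatnonzero(t.roles == AtomRole.WATER_O)
        h_idx = np.flatnonzero(t.roles == AtomRole.WATER_H)
        if o_idx.size == 0 or h_idx.size != 2 * o_idx.size:
            raise ValueError("water needs one O and two H per molecule")
        order_o = o_idx[np.argsort(t.mol_ids[o_idx], kind="stable")]
        order_h = h_idx[np.argsort(t.mol_ids[h_idx], kind="stable")]

    zp_all, ang_all = [], []
    for frame in traj.frames:
        if species == "DMSO":
            o = frame.positions[order_o]
            s = frame.positions[order_s]
            dip = minimum_image(s - o, frame.box)
            ref_z = o[:, 2] + 0.5 * dip[:, 2]  # molecule midpoint
        else:
            o = frame.positions[order_o]
            h = frame.positions[order_h].reshape(-1, 2, 3)
            b = minimum_image(h - o[:, None, :], frame.box)
            b /= np.linalg.norm(b, axis=-1, keepdims=True)
            dip = b.sum(axis=1)
            ref_z = o[:, 2]
        nrm = np.linalg.norm(dip, axis=-1)
        dip = dip / nrm[:, None]
        zp = scaling.to_scaled(ref_z)
        outward = np.where(zp >= 0, 1.0, -1.0)
        ang = np.degrees(np.arccos(np.clip(dip[:, 2] * outward, -1.0, 1.0)))
        zp_all.append(zp)
        ang_all.append(ang)
    zp = np.concatenate(zp_all)
    ang = np.concatenate(ang_all)

    lo = math.floor(zp.min() / bin_width) * bin_width
    hi = math.ceil(zp.max() / bin_width) * bin_width
    nb = max(int(round((hi - lo) / bin_width)), 1)
    edges = np.linspace(lo, lo + nb * bin_width, nb + 1)
    which = np.clip(np.digitize(zp, edges) - 1, 0, nb - 1)
    n_samples = np.bincount(which, minlength=nb)
    sums = np.bincount(which, weights=ang, minlength=nb)
    mean = np.divide(sums, n_samples, out=np.full(nb, np.nan),
                     where=n_samples > 0)
    return OrientationProfile(species=species,
                              bin_centers=0.5 * (edges[:-1] + edges[1:]),
                              mean_angle_deg=mean, n_samples=n_samples)
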