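"""Shared data model and coordinate I/O for solvated bilayer configurations.

The unit every analysis consumes is a :class:`BilayerFrame`: wrapped particle
positions (nm), a rectangular box, and a per-atom :class:`AtomRole` describing
what each site *means* to the analyses (phosphate marker, water oxygen, DMSO
sulfur, tail carbon, ...).  Roles decouple the analyses from force-field atom
naming: they are assigned from a user-overridable role map keyed on
(residue name, atom name).

Coordinates are internally in nm (GRO native); PDB input (Angstrom) is
converted on read.  The bilayer normal is fixed to z throughout.
"""

from __future__ import annotations

import dataclasses
import enum
import re
import warnings
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "MoleculeKind",
    "AtomRole",
    "AtomRecord",
    "Topology",
    "BilayerFrame",
    "Trajectory",
    "LeafletAssignment",
    "FormatError",
    "ConfigurationError",
    "read_gro",
    "write_gro",
    "read_pdb",
    "assign_roles",
    "assign_leaflets",
    "default_role_map",
    "load_role_map",
    "minimum_image",
]


class FormatError(ValueError):
    """A coordinate file violates the expected dialect."""


class ConfigurationError(ValueError):
    """Roles/topology are inconsistent with what an analysis requires."""


class MoleculeKind(enum.IntEnum):
    DOPC = 0
    CHOL = 1
    WATER = 2
    DMSO = 3
    OTHER = 4


class AtomRole(enum.IntEnum):
    NONE = 0
    PHOSPHATE_MARKER = 1
    CHOL_HYDROXYL_O = 2
    WATER_O = 3
    WATER_H = 4
    DMSO_S = 5
    DMSO_O = 6
    DMSO_C = 7
    TAIL_CARBON = 8
    HEAD_OTHER = 9


_KIND_FROM_RESNAME = {
    "DOPC": MoleculeKind.DOPC,
    "CHOL": MoleculeKind.CHOL,
    "CHL1": MoleculeKind.CHOL,
    "SOL": MoleculeKind.WATER,
    "WAT": MoleculeKind.WATER,
    "TIP3": MoleculeKind.WATER,
    "SPC": MoleculeKind.WATER,
    "DMSO": MoleculeKind.DMSO,
}

_RESNAME_FROM_KIND = {
    MoleculeKind.DOPC: "DOPC",
    MoleculeKind.CHOL: "CHOL",
    MoleculeKind.WATER: "SOL",
    MoleculeKind.DMSO: "DMSO",
    MoleculeKind.OTHER: "UNK",
}

# Masses in u.  United-atom carbons carry their implicit hydrogens
# (CH2 = 14.027, CH3 = 15.035); the phosphate marker is the P atom, the
# Chol hydroxyl marker an OH group.
_ROLE_MASS = {
    AtomRole.NONE: 0.0,
    AtomRole.PHOSPHATE_MARKER: 30.974,
    AtomRole.CHOL_HYDROXYL_O: 17.007,
    AtomRole.WATER_O: 15.999,
    AtomRole.WATER_H: 1.008,
    AtomRole.DMSO_S: 32.06,
    AtomRole.DMSO_O: 15.999,
    AtomRole.DMSO_C: 15.035,  # methyl
    AtomRole.TAIL_CARBON: 14.027,  # CH2; terminal CH3 handled separately
    AtomRole.HEAD_OTHER: 13.019,
}

_TAIL_CH3 = 15.035

# Canonical atom naming emitted by the synthetic generator and understood by
# the default role map: DOPC tails C1A..C18A / C1B..C18B, Chol ring-axis
# carbons CA1..CA4.
_DOPC_TAIL_RE = re.compile(r"^C(\d+)([AB])$")
_CHOL_AXIS_RE = re.compile(r"^CA(\d+)$")


def default_role_map() -> dict:
    """Role map for the common DOPC/CHOL/SPC/DMSO atom naming conventions.

    Keys are residue names, values map atom names to role names.  Tail
    carbons are matched by pattern (see module docstring) rather than listed
    one by one.
    """
    return {
        "DOPC": {"P": "phosphate_marker", "P8": "phosphate_marker"},
        "CHOL": {"O3": "chol_hydroxyl_o", "OH": "chol_hydroxyl_o"},
        "SOL": {"OW": "water_o", "HW1": "water_h", "HW2": "water_h"},
        "DMSO": {"S": "dmso_s", "O": "dmso_o", "C1": "dmso_c", "C2": "dmso_c"},
    }


def load_role_map(path) -> dict:
    """Load a role map from a YAML file with the same nested layout as
    :func:`default_role_map`."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"role map {path!r} must be a mapping")
    return data


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, chemistry-free role, and position (nm)."""

    atom_id: int
    molecule_id: int
    molecule_kind: MoleculeKind
    atom_name: str
    role: AtomRole
    tail_index: tuple | None  # (chain, carbon position) iff TAIL_CARBON
    position: np.ndarray


@dataclasses.dataclass
class Topology:
    """Per-atom static arrays shared by every frame of a trajectory."""

    atom_ids: np.ndarray
    mol_ids: np.ndarray
    mol_kinds: np.ndarray  # MoleculeKind values
    atom_names: np.ndarray  # dtype '<U5'
    roles: np.ndarray  # AtomRole values
    tail_chain: np.ndarray  # -1 where not a tail carbon
    tail_pos: np.ndarray  # -1 where not a tail carbon
    masses: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_ids)
        for name in ("mol_ids", "mol_kinds", "atom_names", "roles",
                     "tail_chain", "tail_pos", "masses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology array {name!r} has wrong length")
        # an atom's molecule_kind is shared by its whole molecule
        order = np.argsort(self.mol_ids, kind="stable")
        mids = self.mol_ids[order]
        kinds = self.mol_kinds[order]
        boundaries = np.flatnonzero(np.diff(mids) == 0)
        if np.any(kinds[boundaries] != kinds[boundaries + 1]):
            raise ValueError("a molecule mixes molecule kinds")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def role_counts(self) -> dict:
        return {AtomRole(r).name: int(c)
                for r, c in zip(*np.unique(self.roles, return_counts=True))}

    def mol_kind_of(self) -> dict:
        """molecule id -> MoleculeKind (first atom wins; molecules are pure)."""
        mids, first = np.unique(self.mol_ids, return_index=True)
        return dict(zip(mids.tolist(), self.mol_kinds[first].tolist()))


@dataclasses.dataclass
class BilayerFrame:
    """One configuration: positions wrapped to [0, L) per axis, box in nm."""

    topology: Topology
    positions: np.ndarray  # (n_atoms, 3), nm
    box: np.ndarray  # (Lx, Ly, Lz), nm
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.shape != (self.topology.n_atoms, 3):
            raise ValueError("positions shape does not match topology")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box components must be positive")

    @property
    def area(self) -> float:
        """Membrane (in-plane) area Lx*Ly in nm^2."""
        return float(self.box[0] * self.box[1])

    def wrapped(self) -> "BilayerFrame":
        pos = np.mod(self.positions, self.box)
        return BilayerFrame(self.topology, pos, self.box.copy(), self.time)

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        t = self.topology
        for i in range(t.n_atoms):
            ti = ((int(t.tail_chain[i]), int(t.tail_pos[i]))
                  if t.roles[i] == AtomRole.TAIL_CARBON else None)
            yield AtomRecord(int(t.atom_ids[i]), int(t.mol_ids[i]),
                             MoleculeKind(int(t.mol_kinds[i])),
                             str(t.atom_names[i]), AtomRole(int(t.roles[i])),
                             ti, self.positions[i])


@dataclasses.dataclass
class Trajectory:
    """Ordered frames sharing one topology; times strictly increasing."""

    frames: list
    frame_interval: float = 1.0  # ps
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        n0 = self.frames[0].topology.n_atoms
        for f in self.frames:
            if f.topology.n_atoms != n0:
                raise FormatError("frames do not share topology (atom counts differ)")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def topology(self) -> Topology:
        return self.frames[0].topology

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# geometry helpers

def minimum_image(delta: np.ndarray, box: np.ndarray,
                  axes: Sequence[int] = (0, 1, 2)) -> np.ndarray:
    """Minimum-image displacement(s) for a rectangular periodic box.

    ``axes`` restricts the convention, e.g. ``(0, 1)`` for in-plane-only
    periodicity as used by the pore detector.
    """
    delta = np.array(delta, dtype=float, copy=True)
    for ax in axes:
        delta[..., ax] -= box[ax] * np.round(delta[..., ax] / box[ax])
    return delta


# ---------------------------------------------------------------------------
# GRO I/O (fixed-column dialect, nm; concatenated frames supported)

def _parse_gro_frame(lines, start, path):
    title = lines[start]
    try:
        natoms = int(lines[start + 1].strip())
    except (IndexError, ValueError):
        raise FormatError(f"{path}:{start + 2}: expected an atom count")
    end = start + 2 + natoms
    if end >= len(lines) + 1 or end > len(lines):
        raise FormatError(f"{path}: truncated frame starting at line {start + 1}")
    resids = np.empty(natoms, dtype=int)
    resnames = np.empty(natoms, dtype="<U5")
    names = np.empty(natoms, dtype="<U5")
    pos = np.empty((natoms, 3))
    for i in range(natoms):
        ln = lines[start + 2 + i]
        try:
            resids[i] = int(ln[0:5])
            resnames[i] = ln[5:10].strip()
            names[i] = ln[10:15].strip()
            pos[i, 0] = float(ln[20:28])
            pos[i, 1] = float(ln[28:36])
            pos[i, 2] = float(ln[36:44])
        except (ValueError, IndexError):
            raise FormatError(f"{path}:{start + 3 + i}: malformed GRO atom line")
    try:
        box_fields = [float(x) for x in lines[end].split()]
    except (IndexError, ValueError):
        raise FormatError(f"{path}:{end + 1}: malformed GRO box line")
    if len(box_fields) < 3:
        raise FormatError(f"{path}:{end + 1}: box line needs >= 3 numbers")
    if len(box_fields) > 3 and any(abs(v) > 1e-9 for v in box_fields[3:]):
        raise FormatError(f"{path}:{end + 1}: triclinic boxes are not supported")
    time = None
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            time = None
    return (resids, resnames, names, pos, np.array(box_fields[:3]), time), end + 1


def _topology_from_names(resids, resnames, names) -> Topology:
    n = len(resids)
    kinds = np.array([_KIND_FROM_RESNAME.get(r, MoleculeKind.OTHER)
                      for r in resnames], dtype=int)
    # residue ids in GRO wrap at 100000 and may repeat across species; build
    # molecule ids from (resid, resname) change points
    change = np.ones(n, dtype=bool)
    change[1:] = (resids[1:] != resids[:-1]) | (resnames[1:] != resnames[:-1])
    mol_ids = np.cumsum(change) - 1
    return Topology(
        atom_ids=np.arange(n),
        mol_ids=mol_ids,
        mol_kinds=kinds,
        atom_names=np.asarray(names, dtype="<U5"),
        roles=np.zeros(n, dtype=int),
        tail_chain=np.full(n, -1, dtype=int),
        tail_pos=np.full(n, -1, dtype=int),
        masses=np.zeros(n),
    )


def read_gro(path) -> Trajectory:
    """Read a (possibly concatenated multi-frame) GRO file.

    Positions come back in nm, the box from the GRO box line; atom and
    residue names are preserved.  Roles are all NONE until
    :func:`assign_roles` is applied.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    cursor = 0
    raw = []
    while cursor < len(lines) and lines[cursor].strip() != "":
        parsed, cursor = _parse_gro_frame(lines, cursor, str(path))
        raw.append(parsed)
    if not raw:
        raise FormatError(f"{path}: no frames found")
    n0 = len(raw[0][0])
    for k, (resids, *_rest) in enumerate(raw):
        if len(resids) != n0:
            raise FormatError(f"{path}: frame {k} has {len(resids)} atoms, "
                              f"frame 0 has {n0}")
    topo = _topology_from_names(*raw[0][:3])
    times = [r[5] for r in raw]
    if any(t is None for t in times) or len(set(times)) != len(times):
        times = [float(k) for k in range(len(raw))]
    for (resids, resnames, names, pos, box, _t), t in zip(raw, times):
        frames.append(BilayerFrame(topo, pos, box, time=t))
    interval = times[1] - times[0] if len(times) > 1 else 1.0
    return Trajectory(frames, frame_interval=interval)


def write_gro(traj, path, title: str = "dmsopore configuration") -> None:
    """Write a Trajectory (or single BilayerFrame) as concatenated GRO."""
    if isinstance(traj, BilayerFrame):
        traj = Trajectory([traj])
    path = Path(path)
    t = traj.topology
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{title}, t= {frame.time:.3f}\n")
            fh.write(f"{t.n_atoms:5d}\n")
            for i in range(t.n_atoms):
                resid = (int(t.mol_ids[i]) + 1) % 100000
                resname = _RESNAME_FROM_KIND[MoleculeKind(int(t.mol_kinds[i]))]
                x, y, z = frame.positions[i]
                fh.write(f"{resid:5d}{resname:<5s}{str(t.atom_names[i]):>5s}"
                         f"{(int(t.atom_ids[i]) + 1) % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}"
                     f"{frame.box[2]:10.5f}\n")


def read_pdb(path) -> Trajectory:
    """Minimal multi-MODEL PDB reader (Angstrom converted to nm)."""
    path = Path(path)
    models = [[]]
    box = None
    for ln in path.read_text().splitlines():
        rec = ln[:6].strip()
        if rec == "CRYST1":
            box = np.array([float(ln[6:15]), float(ln[15:24]),
                            float(ln[24:33])]) / 10.0
        elif rec in ("ATOM", "HETATM"):
            try:
                models[-1].append((
                    ln[12:16].strip(), ln[17:21].strip(), int(ln[22:26]),
                    float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0,
                    float(ln[46:54]) / 10.0))
            except ValueError:
                raise FormatError(f"{path}: malformed ATOM record: {ln!r}")
        elif rec == "ENDMDL":
            models.append([])
    models = [m for m in models if m]
    if not models:
        raise FormatError(f"{path}: no ATOM records")
    if box is None:
        raise FormatError(f"{path}: CRYST1 record required")
    names = np.array([a[0] for a in models[0]], dtype="<U5")
    resnames = np.array([a[1] for a in models[0]], dtype="<U5")
    resids = np.array([a[2] for a in models[0]], dtype=int)
    topo = _topology_from_names(resids, resnames, names)
    frames = []
    for k, m in enumerate(models):
        if len(m) != len(names):
            raise FormatError(f"{path}: MODEL {k + 1} atom count differs")
        pos = np.array([[a[3], a[4], a[5]] for a in m])
        frames.append(BilayerFrame(topo, pos, box, time=float(k)))
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# roles

def _role_from_name(kind: int, name: str, role_map: Mapping) -> tuple:
    """Return (AtomRole, tail_chain, tail_pos) for one atom."""
    resname = _RESNAME_FROM_KIND[MoleculeKind(kind)]
    entry = role_map.get(resname, {})
    if name in entry:
        return AtomRole[entry[name].upper()], -1, -1
    if kind == MoleculeKind.DOPC:
        m = _DOPC_TAIL_RE.match(name)
        if m:
            return AtomRole.TAIL_CARBON, "AB".index(m.group(2)), int(m.group(1))
    if kind == MoleculeKind.CHOL:
        m = _CHOL_AXIS_RE.match(name)
        if m:
            # Chol ring-axis carbons are tracked as a single tail chain so the
            # tilt analysis can find "hydroxyl -> last ring-axis carbon"
            return AtomRole.TAIL_CARBON, 0, int(m.group(1))
    return AtomRole.NONE, -1, -1


def assign_roles(traj: Trajectory, role_map: Mapping | None = None) -> Trajectory:
    """Assign an :class:`AtomRole` (and mass) to every atom, in place.

    Unmapped atoms get NONE; DMSO molecules left entirely unmapped trigger a
    warning; a DOPC molecule with no phosphate marker is a configuration
    error because the P-P distance would be undefined.
    """
    if role_map is None:
        role_map = default_role_map()
    t = traj.topology
    roles = np.zeros(t.n_atoms, dtype=int)
    chain = np.full(t.n_atoms, -1, dtype=int)
    pos = np.full(t.n_atoms, -1, dtype=int)
    cache: dict = {}
    for i in range(t.n_atoms):
        key = (int(t.mol_kinds[i]), str(t.atom_names[i]))
        if key not in cache:
            cache[key] = _role_from_name(key[0], key[1], role_map)
        roles[i], chain[i], pos[i] = cache[key]
    t.roles = roles
    t.tail_chain = chain
    t.tail_pos = pos

    masses = np.array([_ROLE_MASS[AtomRole(int(r))] for r in roles])
    # terminal tail carbon of each chain is a CH3
    tail = roles == AtomRole.TAIL_CARBON
    if np.any(tail):
        dopc_tail = tail & (t.mol_kinds == MoleculeKind.DOPC)
        if np.any(dopc_tail):
            last = pos[dopc_tail].max()
            masses[dopc_tail & (pos == last)] = _TAIL_CH3
    t.masses = masses

    dmso_mols = t.mol_kinds == MoleculeKind.DMSO
    if np.any(dmso_mols) and not np.any(roles[dmso_mols] != AtomRole.NONE):
        warnings.warn("role map has no DMSO entries; DMSO atoms tagged NONE",
                      stacklevel=2)
    dopc = t.mol_kinds == MoleculeKind.DOPC
    if np.any(dopc):
        has_p = set(t.mol_ids[dopc & (roles == AtomRole.PHOSPHATE_MARKER)])
        all_dopc = set(t.mol_ids[dopc])
        missing = all_dopc - has_p
        if missing:
            raise ConfigurationError(
                f"{len(missing)} DOPC molecule(s) have no phosphate marker; "
                "P-P distance would be undefined (check the role map)")
    return traj


# ---------------------------------------------------------------------------
# leaflets

UPPER = 1
LOWER = -1
UNASSIGNED = 0


@dataclasses.dataclass
class LeafletAssignment:
    """Per-molecule leaflet labels for one frame.

    ``leaflet[mol_id]`` is +1 (upper), -1 (lower) or 0; the outward normal
    of the upper leaflet is +z.  ``intact`` is False when all phosphates sit
    on one side of the midplane (collapsed system).
    """

    mol_ids: np.ndarray
    leaflet: np.ndarray
    midplane_z: float
    intact: bool

    def outward_normal(self, leaflet_sign: int) -> np.ndarray:
        return np.array([0.0, 0.0, float(np.sign(leaflet_sign))])

    def as_dict(self) -> dict:
        return dict(zip(self.mol_ids.tolist(), self.leaflet.tolist()))

    def count(self, sign: int) -> int:
        return int(np.sum(self.leaflet == sign))


def assign_leaflets(frame: BilayerFrame) -> LeafletAssignment:
    """Split lipids/Chol into leaflets about the mean phosphate z.

    The midplane is the mean z of all phosphate markers; the reference atom
    (phosphate for DOPC, hydroxyl O for Chol) decides the side.  A molecule
    exactly at the midplane goes to the LOWER leaflet (deterministic
    tie-break).
    """
    t = frame.topology
    z = frame.positions[:, 2]
    p_mask = t.roles == AtomRole.PHOSPHATE_MARKER
    if np.sum(p_mask) < 2:
        raise ConfigurationError("need >= 2 phosphate markers to assign leaflets")
    midplane = float(np.mean(z[p_mask]))

    ref_mask = p_mask | (t.roles == AtomRole.CHOL_HYDROXYL_O)
    mids = np.unique(t.mol_ids)
    leaflet = np.zeros(len(mids), dtype=int)
    index = {m: i for i, m in enumerate(mids.tolist())}
    for mol, zref in zip(t.mol_ids[ref_mask], z[ref_mask]):
        leaflet[index[int(mol)]] = UPPER if zref > midplane else LOWER
    intact = bool(np.any(z[p_mask] > midplane) and np.any(z[p_mask] <= midplane)
                  and np.ptp(z[p_mask]) > 0)
    return LeafletAssignment(mids, leaflet, midplane, intact)
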