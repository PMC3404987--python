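"""Statistical generator of solvated DOPC/Chol bilayer configurations.

Configurations are *sampled*, not simulated: there are no forces and no
dynamics.  Frames are independent draws from distributions whose tunable
parameters (chain order, tilt, DMSO interfacial localization, dipole
orientation bias, water penetration into the core) are exactly the
observables the analysis modules measure, which gives every downstream
stage a known ground truth.  Transmembrane water defects are planted, not
emergent.

Geometry conventions
--------------------
The bilayer midplane sits at Lz/2; phosphate planes at +-``leaflet_z_offset``
around it.  The planned scaled coordinate is Z' = (z - z_mid)/leaflet_z_offset,
so the phosphate planes are at Z' = +-1 by construction (the analysis
re-derives the scaling from the phosphate density maxima).

Chain-order control
-------------------
Each acyl chain gets a director drawn from a Watson-type axial distribution
p(u) ~ exp(kappa (u.n)^2) about the inward leaflet normal; kappa is solved by
root-finding so the mean director tilt matches ``target_tail_tilt_deg``.
An ideal tetrahedral zigzag of 18 united-atom carbons is laid along the
director and its interior carbons receive transverse Gaussian noise whose
amplitude is solved (Monte Carlo with common random numbers) so the implied
deuterium order parameter matches ``target_mean_scd``.  Chain endpoints stay
noise-free, so the end-to-end tilt remains exactly Watson-distributed and the
two targets decouple.
"""

from __future__ import annotations

import dataclasses
import functools
import math

import numpy as np
from scipy.optimize import brentq

from .model_io import (
    AtomRole,
    BilayerFrame,
    MoleculeKind,
    Topology,
    Trajectory,
)

__all__ = [
    "GeneratorSpec",
    "PorePlan",
    "build_bilayer",
    "place_solvent",
    "plant_pore",
    "generate_trajectory",
    "solvent_slab_from_potential",
    "isotropic_dmso_box",
    "round_half_away",
]

R_GAS = 8.314e-3  # kJ mol^-1 K^-1

_BOND_CC = 0.153  # nm
_COS_A = math.sqrt(2.0 / 3.0)  # zigzag half-angle: cos(35.26 deg)
_SIN_A = math.sqrt(1.0 / 3.0)
_N_TAIL_C = 18
_OH_BOND = 0.1  # nm, water O-H
_HOH_HALF = math.radians(104.52 / 2.0)
_OS_BOND = 0.153  # nm, DMSO O->S
_EXCLUSION = 0.25  # nm, coarse excluded-volume radius between placement anchors


class GenerationError(RuntimeError):
    """Raised when a spec cannot be realized (e.g. box too small)."""


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (reproduces 128/32 at 20 mol%)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclasses.dataclass
class PorePlan:
    """A transmembrane water defect to plant.

    HYDROPHOBIC_COLUMN: bare single-file water column.
    HYDROPHILIC_PORE: column additionally lined by relocated lipid
    headgroup / Chol hydroxyl atoms.
    """

    kind: str  # "HYDROPHOBIC_COLUMN" | "HYDROPHILIC_PORE"
    radius: float  # nm
    n_lining_headgroups: int = 0
    frames_present: tuple = (0, 0)  # inclusive (first, last) frame indices
    center_xy: tuple | None = None  # defaults to box center

    def __post_init__(self) -> None:
        if self.kind not in ("HYDROPHOBIC_COLUMN", "HYDROPHILIC_PORE"):
            raise ValueError(f"unknown pore kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("pore radius must be > 0")
        if self.kind == "HYDROPHOBIC_COLUMN" and self.n_lining_headgroups != 0:
            raise ValueError("a hydrophobic column has no lining headgroups")


@dataclasses.dataclass
class GeneratorSpec:
    """All knobs of the generator; ``seed`` fixes every random draw.

    Composition defaults follow the simulated systems the analyses target:
    128 DOPC with 20 mol% Chol (32 molecules) and 6186 solvent molecules,
    with the DMSO mole fraction of the solvent as the swept variable.
    """

    n_dopc: int = 128
    chol_mol_fraction: float = 0.20
    n_solvent: int = 6186
    dmso_solvent_mol_fraction: float = 0.05
    box_xy: float = 6.67  # nm; 6.67^2 = 44.5 nm^2, the DMSO-free area
    box_z: float = 9.0  # nm
    leaflet_z_offset: float = 2.085  # nm; P-P distance 4.17 nm when doubled
    target_mean_scd: float = 0.1528
    target_tail_tilt_deg: float = 28.26
    target_chol_tilt_deg: float = 30.88
    dmso_interface_width: float = 0.25  # nm
    dmso_interface_fraction: float = 0.55
    dmso_dipole_mean_angle: float | None = 110.0  # deg; None => isotropic
    water_core_penetration: float = 0.05  # relative density at Z'=0
    water_interface_dipole_mean_angle: float | None = 100.0  # deg
    undulation_amplitude: float = 0.0  # nm
    pore_plan: PorePlan | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chol_mol_fraction", "dmso_solvent_mol_fraction",
                     "dmso_interface_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_dopc < 0 or self.n_solvent < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.box_xy <= 0 or self.box_z <= 0:
            raise ValueError("box dimensions must be > 0")
        if not 0.0 <= self.target_mean_scd <= 0.5:
            raise ValueError("target_mean_scd must be in [0, 0.5]")
        if not 0.0 <= self.water_core_penetration <= 1.0:
            raise ValueError("water_core_penetration must be in [0, 1]")

    @property
    def n_chol(self) -> int:
        """Chol count from its mole fraction of all lipids (ties away from 0)."""
        f = self.chol_mol_fraction
        if f >= 1.0:
            raise ValueError("chol_mol_fraction must be < 1 with DOPC present")
        return round_half_away(f * self.n_dopc / (1.0 - f))

    @property
    def n_dmso(self) -> int:
        return round_half_away(self.dmso_solvent_mol_fraction * self.n_solvent)

    @property
    def n_water(self) -> int:
        return self.n_solvent - self.n_dmso


# ---------------------------------------------------------------------------
# axial (Watson-type) distribution: p(cos t) ~ exp(kappa cos^2 t) on [0, 1]

def _watson_moments(kappa: float):
    c = np.linspace(0.0, 1.0, 4001)
    w = np.exp(kappa * (c * c - (1.0 if kappa > 0 else 0.0)))
    norm = np.trapezoid(w, c)
    theta = np.degrees(np.arccos(np.clip(c, -1, 1)))
    mean_angle = np.trapezoid(theta * w, c) / norm
    p2 = np.trapezoid(0.5 * (3 * c * c - 1) * w, c) / norm
    return mean_angle, p2


def solve_watson_kappa(target_mean_angle_deg: float) -> float:
    """Concentration with hemisphere mean tilt equal to the target (deg)."""
    if not 0.0 < target_mean_angle_deg < 90.0:
        raise ValueError("target mean angle must be in (0, 90) degrees")

    def f(k):
        return _watson_moments(k)[0] - target_mean_angle_deg

    lo, hi = -200.0, 200.0
    while f(hi) > 0:
        hi *= 2
        if hi > 1e7:
            raise RuntimeError("cannot bracket Watson concentration")
    return brentq(f, lo, hi, xtol=1e-10)


def _sample_watson_cos(kappa: float, n: int, rng) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 32
        c = rng.random(m)
        if kappa >= 0:
            acc = rng.random(m) < np.exp(kappa * (c * c - 1.0))
        else:
            acc = rng.random(m) < np.exp(kappa * c * c)
        c = c[acc][: n - filled]
        out[filled:filled + c.size] = c
        filled += c.size
    return out


def _unit_from_cos_az(cos_t, az):
    sin_t = np.sqrt(np.clip(1.0 - cos_t * cos_t, 0.0, 1.0))
    return np.stack([sin_t * np.cos(az), sin_t * np.sin(az), cos_t], axis=-1)


def _perp_frame(u):
    """Two unit vectors completing a right-handed frame with u (vectorized)."""
    ref = np.zeros_like(u)
    small_z = np.abs(u[..., 2]) < 0.9
    ref[..., 2] = np.where(small_z, 1.0, 0.0)
    ref[..., 0] = np.where(small_z, 0.0, 1.0)
    p = np.cross(ref, u)
    p /= np.linalg.norm(p, axis=-1, keepdims=True)
    q = np.cross(u, p)
    return p, q


# ---------------------------------------------------------------------------
# chain construction and the implied order parameter

def _build_chains(u, az, noise, sigma):
    """Zigzag chains of 18 carbons along directors ``u``.

    u : (M, 3) unit directors; az : (M,) zigzag-plane azimuths;
    noise : (M, 18, 2) standard normals (rows 0 and 17 ignored);
    returns positions (M, 18, 3) relative to the first carbon.
    """
    n_c = noise.shape[1]
    p, q = _perp_frame(u)
    e1 = np.cos(az)[:, None] * p + np.sin(az)[:, None] * q
    e2 = -np.sin(az)[:, None] * p + np.cos(az)[:, None] * q
    signs = (-1.0) ** np.arange(n_c - 1)
    bonds = (_BOND_CC * _COS_A * u[:, None, :]
             + (_BOND_CC * _SIN_A) * signs[None, :, None] * e1[:, None, :])
    pos = np.zeros((u.shape[0], n_c, 3))
    pos[:, 1:, :] = np.cumsum(bonds, axis=1)
    if sigma > 0:
        disp = sigma * (noise[:, :, 0:1] * e1[:, None, :]
                        + noise[:, :, 1:2] * e2[:, None, :])
        pos[:, 1:-1, :] += disp[:, 1:-1, :]
    return pos


_COS_B = 1.0 / math.sqrt(3.0)  # half H-C-H tetrahedral angle
_SIN_B = math.sqrt(2.0 / 3.0)


def implied_minus_scd(pos) -> float:
    """-S_CD implied by chain coordinates via tetrahedral H reconstruction.

    This is the geometric definition the ordering analysis also uses; here it
    acts on raw (M, n_carbons, 3) arrays so the generator can calibrate its
    noise amplitude without any trajectory plumbing.
    """
    b = pos[:, 1:, :] - pos[:, :-1, :]
    a = b[:, 1:, :] + b[:, :-1, :]
    d = 0.5 * (b[:, :-1, :] - b[:, 1:, :])
    a_hat = a / np.linalg.norm(a, axis=-1, keepdims=True)
    d_perp = d - np.sum(d * a_hat, axis=-1, keepdims=True) * a_hat
    nrm = np.linalg.norm(d_perp, axis=-1, keepdims=True)
    d_hat = d_perp / np.where(nrm > 1e-12, nrm, 1.0)
    n_hat = np.cross(a_hat, d_hat)
    cz1 = _COS_B * d_hat[..., 2] + _SIN_B * n_hat[..., 2]
    cz2 = _COS_B * d_hat[..., 2] - _SIN_B * n_hat[..., 2]
    scd = 0.5 * (3.0 * 0.5 * (cz1 ** 2 + cz2 ** 2) - 1.0)
    return float(-np.mean(scd))


@functools.lru_cache(maxsize=32)
def calibrate_chain_order(target_scd: float, target_tilt_deg: float):
    """Solve (kappa, sigma) for the chain-order model.

    kappa sets the Watson director concentration so the mean director tilt is
    ``target_tilt_deg``; sigma is the interior transverse noise (nm) solved so
    the implied mean -S_CD equals ``target_scd``.  The Monte Carlo uses a
    fixed internal seed and common random numbers across sigma values, so the
    result depends only on the targets.
    """
    kappa = solve_watson_kappa(target_tilt_deg)
    rng = np.random.default_rng(987654321)
    m = 20_000
    cos_t = _sample_watson_cos(kappa, m, rng)
    az_u = rng.uniform(0, 2 * np.pi, m)
    u = _unit_from_cos_az(cos_t, az_u)
    az = rng.uniform(0, 2 * np.pi, m)
    noise = rng.standard_normal((m, _N_TAIL_C, 2))

    def implied(sigma):
        return implied_minus_scd(_build_chains(u, az, noise, sigma))

    s0 = implied(0.0)
    if target_scd > s0 + 1e-4:
        raise GenerationError(
            f"target_mean_scd={target_scd} unreachable: tilt distribution "
            f"alone caps -S_CD at {s0:.4f}; lower the tilt target")
    if target_scd >= s0:
        return kappa, 0.0
    sigma = brentq(lambda s: implied(s) - target_scd, 0.0, 2.0, xtol=1e-5)
    return kappa, float(sigma)


# ---------------------------------------------------------------------------
# topology assembly

class _Builder:
    """Accumulates atoms molecule by molecule in emission order."""

    def __init__(self) -> None:
        self.mol_ids: list = []
        self.kinds: list = []
        self.names: list = []
        self.roles: list = []
        self.tchain: list = []
        self.tpos: list = []
        self.masses: list = []
        self.positions: list = []
        self._mol = -1

    def new_molecule(self, kind) -> int:
        self._mol += 1
        self._kind = int(kind)
        return self._mol

    def atom(self, name, role, xyz, mass, tchain=-1, tpos=-1) -> None:
        self.mol_ids.append(self._mol)
        self.kinds.append(self._kind)
        self.names.append(name)
        self.roles.append(int(role))
        self.tchain.append(tchain)
        self.tpos.append(tpos)
        self.masses.append(mass)
        self.positions.append(xyz)

    def frame(self, box, time=0.0) -> BilayerFrame:
        n = len(self.mol_ids)
        topo = Topology(
            atom_ids=np.arange(n),
            mol_ids=np.array(self.mol_ids),
            mol_kinds=np.array(self.kinds),
            atom_names=np.array(self.names, dtype="<U5"),
            roles=np.array(self.roles),
            tail_chain=np.array(self.tchain),
            tail_pos=np.array(self.tpos),
            masses=np.array(self.masses),
        )
        pos = np.mod(np.array(self.positions), np.asarray(box))
        return BilayerFrame(topo, pos, np.asarray(box, dtype=float), time)


_M_CH2, _M_CH3 = 14.027, 15.035
_M_P, _M_OH, _M_O, _M_H, _M_S = 30.974, 17.007, 15.999, 1.008, 32.06


def _undulation(spec, x, y):
    if spec.undulation_amplitude == 0.0:
        return np.zeros_like(np.asarray(x, dtype=float))
    kx = 2 * np.pi / spec.box_xy
    return spec.undulation_amplitude * np.cos(kx * x) * np.cos(kx * y)


def _leaflet_sites(n, box_xy, rng):
    """Jittered grid of n in-plane sites, randomly permuted."""
    g = int(math.ceil(math.sqrt(n)))
    cell = box_xy / g
    ix, iy = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    xy = np.stack([(ix.ravel() + 0.5) * cell, (iy.ravel() + 0.5) * cell], axis=1)
    xy += rng.uniform(-0.3 * cell, 0.3 * cell, size=xy.shape)
    return xy[rng.permutation(g * g)[:n]]


def build_bilayer(spec: GeneratorSpec, rng=None) -> BilayerFrame:
    """Build the lipid part of one configuration (no solvent).

    Lipids split evenly between leaflets; each DOPC is a phosphate marker
    plus two 18-carbon united-atom tails, each Chol a hydroxyl oxygen plus
    four ring-axis carbons.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_chol = spec.n_chol
    box = np.array([spec.box_xy, spec.box_xy, spec.box_z])
    z_mid = spec.box_z / 2.0
    h = spec.leaflet_z_offset
    kappa_t, sigma = calibrate_chain_order(spec.target_mean_scd,
                                           spec.target_tail_tilt_deg)
    kappa_c = solve_watson_kappa(spec.target_chol_tilt_deg)

    n_sites_needed = max((spec.n_dopc + 1) // 2 + (n_chol + 1) // 2, 1)
    min_cell = spec.box_xy / math.ceil(math.sqrt(n_sites_needed))
    if spec.n_dopc and min_cell < 0.4:
        raise GenerationError(
            f"box_xy={spec.box_xy} nm too small for "
            f"{n_sites_needed} lipids per leaflet; enlarge the box")

    b = _Builder()
    for sign, n_d, n_c in (
        (+1, spec.n_dopc - spec.n_dopc // 2, n_chol - n_chol // 2),
        (-1, spec.n_dopc // 2, n_chol // 2),
    ):
        sites = _leaflet_sites(n_d + n_c, spec.box_xy, rng) if n_d + n_c else \
            np.zeros((0, 2))
        # DOPC first, then Chol, within each leaflet
        for k in range(n_d):
            x, y = sites[k]
            zp = z_mid + sign * h + _undulation(spec, x, y) \
                + rng.normal(0.0, 0.03)
            b.new_molecule(MoleculeKind.DOPC)
            b.atom("P", AtomRole.PHOSPHATE_MARKER, (x, y, zp), _M_P)
            for chain, letter, dx in ((0, "A", -0.2), (1, "B", 0.2)):
                cos_t = _sample_watson_cos(kappa_t, 1, rng)[0]
                az_u = rng.uniform(0, 2 * np.pi)
                u = _unit_from_cos_az(np.array(cos_t), np.array(az_u))
                u[2] *= -sign  # directors point into the core
                az = rng.uniform(0, 2 * np.pi)
                noise = rng.standard_normal((1, _N_TAIL_C, 2))
                chain_pos = _build_chains(u[None, :], np.array([az]),
                                          noise, sigma)[0]
                start = np.array([x + dx, y, zp - sign * 0.15])
                for ci in range(_N_TAIL_C):
                    mass = _M_CH3 if ci == _N_TAIL_C - 1 else _M_CH2
                    b.atom(f"C{ci + 1}{letter}", AtomRole.TAIL_CARBON,
                           start + chain_pos[ci], mass,
                           tchain=chain, tpos=ci + 1)
        for k in range(n_c):
            x, y = sites[n_d + k]
            zo = z_mid + sign * (h - 0.3) + _undulation(spec, x, y) \
                + rng.normal(0.0, 0.03)
            cos_t = _sample_watson_cos(kappa_c, 1, rng)[0]
            az_u = rng.uniform(0, 2 * np.pi)
            v = _unit_from_cos_az(np.array(cos_t), np.array(az_u))
            v[2] *= -sign
            b.new_molecule(MoleculeKind.CHOL)
            b.atom("O3", AtomRole.CHOL_HYDROXYL_O, (x, y, zo), _M_OH)
            for ci in range(4):
                b.atom(f"CA{ci + 1}", AtomRole.TAIL_CARBON,
                       np.array([x, y, zo]) + 0.25 * (ci + 1) * v,
                       _M_CH2, tchain=0, tpos=ci + 1)
    frame = b.frame(box)
    frame.time = 0.0
    return frame


# ---------------------------------------------------------------------------
# solvent

def _water_rel_density(abs_zp, penetration):
    """Relative water density vs |Z'|: 1 in bulk, log-linear decay to
    ``penetration`` at the bilayer center."""
    abs_zp = np.asarray(abs_zp, dtype=float)
    if penetration <= 0:
        core = np.where(abs_zp < 1.0, 0.0, 1.0)
        return core
    return np.where(abs_zp >= 1.0, 1.0,
                    np.exp(np.log(penetration) * (1.0 - abs_zp)))


def _sample_water_z(n, spec, rng):
    z_mid, h, lz = spec.box_z / 2.0, spec.leaflet_z_offset, spec.box_z
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 64
        z = rng.uniform(0.0, lz, m)
        w = _water_rel_density(np.abs(z - z_mid) / h, spec.water_core_penetration)
        z = z[rng.random(m) < w][: n - filled]
        out[filled:filled + z.size] = z
        filled += z.size
    return out


def _sample_dmso_z(n, spec, rng):
    z_mid, h, lz = spec.box_z / 2.0, spec.leaflet_z_offset, spec.box_z
    interfacial = rng.random(n) < spec.dmso_interface_fraction
    z = np.empty(n)
    n_b = int(np.sum(~interfacial))
    # bulk component: uniform in |Z'| > 1
    zb = np.empty(n_b)
    filled = 0
    while filled < n_b:
        m = 2 * (n_b - filled) + 64
        cand = rng.uniform(0.0, lz, m)
        cand = cand[np.abs(cand - z_mid) > h][: n_b - filled]
        zb[filled:filled + cand.size] = cand
        filled += cand.size
    z[~interfacial] = zb
    # interfacial component: Gaussian centred just below |Z'| = 1
    n_i = n - n_b
    side = np.where(rng.random(n_i) < 0.5, 1.0, -1.0)
    z[interfacial] = (z_mid + side * 0.9 * h
                      + rng.normal(0.0, spec.dmso_interface_width, n_i))
    return np.clip(z, 0.0, lz - 1e-9)


def _sample_polar_angles(n, mean_deg, rng, spread_deg=10.0):
    """Polar angles (rad) vs the outward normal: truncated normal about the
    mean, or isotropic (cos uniform) when mean_deg is None."""
    if mean_deg is None:
        return np.arccos(rng.uniform(-1.0, 1.0, n))
    t = rng.normal(math.radians(mean_deg), math.radians(spread_deg), n)
    return np.clip(t, 0.0, math.pi)


def _dirs_from_polar(theta, az, sign):
    """Unit vectors with polar angle theta vs the *outward* normal
    sign * +z."""
    d = _unit_from_cos_az(np.cos(theta), az)
    d[:, 2] *= sign
    return d


class _AnchorGrid:
    """Spatial hash enforcing the coarse 0.25 nm anchor exclusion."""

    def __init__(self, box, cell=_EXCLUSION):
        self.box = np.asarray(box)
        self.cell = cell
        self.n = np.maximum((self.box / cell).astype(int), 1)
        self.grid: dict = {}

    def _key(self, p):
        return tuple((np.floor(p / self.box * self.n).astype(int) % self.n))

    def insert_many(self, pts) -> None:
        for p in pts:
            self.grid.setdefault(self._key(p), []).append(np.asarray(p))

    def ok(self, p) -> bool:
        kx, ky, kz = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = ((kx + dx) % self.n[0], (ky + dy) % self.n[1],
                           (kz + dz) % self.n[2])
                    for q in self.grid.get(key, ()):
                        d = p - q
                        d[:2] -= self.box[:2] * np.round(d[:2] / self.box[:2])
                        if d @ d < _EXCLUSION ** 2:
                            return False
        return True

    def add_if_ok(self, p) -> bool:
        if self.ok(p):
            self.grid.setdefault(self._key(p), []).append(np.asarray(p))
            return True
        return False


def place_solvent(frame: BilayerFrame, spec: GeneratorSpec,
                  rng=None) -> BilayerFrame:
    """Add water and DMSO to a built bilayer, returning a new frame.

    Water z positions are rejection-sampled from the piecewise density
    (bulk-constant, decaying into the core); DMSO from a bulk + interfacial
    Gaussian mixture.  Dipole orientations follow the configured biases.  Anchor
    sites keep a coarse 0.25 nm exclusion from lipid heavy atoms and from
    each other.
    """
    if spec.n_solvent == 0:
        return frame
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    box = frame.box
    z_mid, h = spec.box_z / 2.0, spec.leaflet_z_offset
    grid = _AnchorGrid(box)
    heavy = frame.positions[frame.topology.masses > 2.0]
    grid.insert_many(heavy)

    b = _Builder()
    # re-emit the lipid atoms so the solvated frame is self-contained
    t = frame.topology
    last_mol = None
    for i in range(t.n_atoms):
        if t.mol_ids[i] != last_mol:
            b.new_molecule(t.mol_kinds[i])
            last_mol = t.mol_ids[i]
        b.atom(str(t.atom_names[i]), t.roles[i], frame.positions[i],
               t.masses[i], t.tail_chain[i], t.tail_pos[i])

    def _place(n, z_sampler):
        placed = []
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise GenerationError(
                    "excluded-volume placement failed; box too crowded")
            z = z_sampler(1)[0]
            p = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]), z])
            if grid.add_if_ok(p):
                placed.append(p)
        return np.array(placed)

    # --- water ---
    n_w = spec.n_water
    if n_w:
        anchors = _place(n_w, lambda m: _sample_water_z(m, spec, rng))
        zp = (anchors[:, 2] - z_mid) / h
        sign = np.where(zp >= 0, 1.0, -1.0)
        interfacial = np.abs(np.abs(zp) - 1.0) < 0.3
        theta = np.arccos(rng.uniform(-1.0, 1.0, n_w))
        if spec.water_interface_dipole_mean_angle is not None:
            theta_i = _sample_polar_angles(
                int(interfacial.sum()), spec.water_interface_dipole_mean_angle,
                rng, spread_deg=15.0)
            theta[interfacial] = theta_i
        dip = _dirs_from_polar(theta, rng.uniform(0, 2 * np.pi, n_w), sign)
        p_perp, _ = _perp_frame(dip)
        ha = _OH_BOND * (math.cos(_HOH_HALF) * dip + math.sin(_HOH_HALF) * p_perp)
        hb = _OH_BOND * (math.cos(_HOH_HALF) * dip - math.sin(_HOH_HALF) * p_perp)
        for k in range(n_w):
            b.new_molecule(MoleculeKind.WATER)
            b.atom("OW", AtomRole.WATER_O, anchors[k], _M_O)
            b.atom("HW1", AtomRole.WATER_H, anchors[k] + ha[k], _M_H)
            b.atom("HW2", AtomRole.WATER_H, anchors[k] + hb[k], _M_H)

    # --- DMSO ---
    n_d = spec.n_dmso
    if n_d:
        anchors = _place(n_d, lambda m: _sample_dmso_z(m, spec, rng))
        zp = (anchors[:, 2] - z_mid) / h
        sign = np.where(zp >= 0, 1.0, -1.0)
        theta = _sample_polar_angles(n_d, spec.dmso_dipole_mean_angle, rng)
        dip = _dirs_from_polar(theta, rng.uniform(0, 2 * np.pi, n_d), sign)
        p_perp, _ = _perp_frame(dip)
        for k in range(n_d):
            s_pos = anchors[k]
            o_pos = s_pos - _OS_BOND * dip[k]
            c1 = s_pos + 0.18 * (0.5 * dip[k] + 0.866 * p_perp[k])
            c2 = s_pos + 0.18 * (0.5 * dip[k] - 0.866 * p_perp[k])
            b.new_molecule(MoleculeKind.DMSO)
            b.atom("S", AtomRole.DMSO_S, s_pos, _M_S)
            b.atom("O", AtomRole.DMSO_O, o_pos, _M_O)
            b.atom("C1", AtomRole.DMSO_C, c1, _M_CH3)
            b.atom("C2", AtomRole.DMSO_C, c2, _M_CH3)

    out = b.frame(box, time=frame.time)
    return out


# ---------------------------------------------------------------------------
# trajectories and planted pores

def generate_trajectory(spec: GeneratorSpec, n_frames: int = 10,
                        frame_interval: float = 100.0) -> Trajectory:
    """Independent frames sharing one topology; applies ``spec.pore_plan``."""
    children = np.random.SeedSequence(spec.seed).spawn(n_frames)
    frames = []
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        f = place_solvent(build_bilayer(spec, rng), spec, rng)
        f.time = k * frame_interval
        frames.append(f)
    topo = frames[0].topology
    frames = [BilayerFrame(topo, f.positions, f.box, f.time) for f in frames]
    traj = Trajectory(frames, frame_interval=frame_interval,
                      metadata={"generator_spec": spec})
    if spec.pore_plan is not None:
        traj = plant_pore(traj, spec.pore_plan, seed=spec.seed)
    return traj


def _column_offsets(n_levels, radius, rng):
    """In-plane offsets of a connected single-file column: a clipped random
    walk inside the planned radius, steps small enough that consecutive
    oxygens stay within the detector's clustering cutoff."""
    off = np.zeros((n_levels, 2))
    for k in range(1, n_levels):
        step = rng.normal(0.0, 0.04, 2)
        cand = off[k - 1] + step
        r = np.hypot(*cand)
        if r > radius:
            cand *= radius / r
        off[k] = cand
    return off


def plant_pore(traj: Trajectory, plan: PorePlan, seed: int = 0) -> Trajectory:
    """Plant a transmembrane water column (optionally headgroup-lined).

    Existing bulk water molecules are relocated into the column (the same
    molecule ids in every planted frame, so defect tracks link), keeping the
    topology unchanged.  Ground truth is recorded in ``Trajectory.metadata``
    under ``"planted"``.
    """
    first, last = plan.frames_present
    if first > last:
        return traj  # empty range: no-op
    if first < 0 or last >= traj.n_frames:
        raise ValueError("frames_present outside the trajectory range")
    box = traj.frames[0].box
    if plan.radius >= min(box[0], box[1]) / 4.0:
        raise ValueError(
            f"pore radius {plan.radius} nm >= box_xy/4; it would "
            "self-interact through the periodic boundaries")

    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 777, first, last]))
    t = traj.topology
    water_o = np.flatnonzero(t.roles == AtomRole.WATER_O)
    if water_o.size == 0:
        raise ValueError("cannot plant a pore without water")

    used: set = set()
    for rec in traj.metadata.get("planted", []):
        used.update(rec["water_mol_ids"])

    f0 = traj.frames[first]
    p = f0.positions[t.roles == AtomRole.PHOSPHATE_MARKER, 2]
    z_mid = float(np.mean(p))
    z_lo = float(np.mean(p[p <= z_mid]))
    z_hi = float(np.mean(p[p > z_mid]))
    levels = np.arange(z_lo, z_hi + 0.125, 0.25)
    n_levels = len(levels)

    center = (np.array(plan.center_xy) if plan.center_xy is not None
              else box[:2] / 2.0)
    offsets = _column_offsets(n_levels, plan.radius, rng)

    # bulk-most unused waters, deterministic order
    cand = [int(m) for m in t.mol_ids[water_o] if int(m) not in used]
    if len(cand) < n_levels:
        raise ValueError("not enough free water molecules to build the column")
    order = np.argsort(np.abs(f0.positions[water_o, 2] - z_mid))[::-1]
    chosen = []
    for idx in order:
        m = int(t.mol_ids[water_o[idx]])
        if m not in used and m not in chosen:
            chosen.append(m)
        if len(chosen) == n_levels:
            break

    lining_atoms = np.flatnonzero(
        (t.roles == AtomRole.PHOSPHATE_MARKER)
        | (t.roles == AtomRole.CHOL_HYDROXYL_O))

    new_frames = []
    for k, f in enumerate(traj.frames):
        if not first <= k <= last:
            new_frames.append(f)
            continue
        pos = f.positions.copy()
        for lvl, mol in enumerate(chosen):
            sel = np.flatnonzero(t.mol_ids == mol)
            o_idx = sel[t.roles[sel] == AtomRole.WATER_O][0]
            o_new = np.array([center[0] + offsets[lvl, 0],
                              center[1] + offsets[lvl, 1], levels[lvl]])
            shift = o_new - pos[o_idx]
            pos[sel] += shift
        if plan.kind == "HYDROPHILIC_PORE" and plan.n_lining_headgroups > 0:
            d = pos[lining_atoms, :2] - center
            d -= box[:2] * np.round(d / box[:2])
            nearest = lining_atoms[np.argsort(np.hypot(d[:, 0], d[:, 1]))]
            ring = nearest[: plan.n_lining_headgroups]
            phis = 2 * np.pi * np.arange(len(ring)) / max(len(ring), 1)
            span = z_hi - z_lo
            z_ring = np.linspace(z_lo + 0.35 * span, z_hi - 0.35 * span,
                                 len(ring))
            for j, ai in enumerate(ring):
                pos[ai] = [center[0] + 0.45 * np.cos(phis[j]),
                           center[1] + 0.45 * np.sin(phis[j]), z_ring[j]]
        pos = np.mod(pos, box)
        new_frames.append(BilayerFrame(t, pos, f.box, f.time))

    meta = dict(traj.metadata)
    planted = list(meta.get("planted", []))
    planted.append({
        "kind": plan.kind,
        "radius": plan.radius,
        "n_lining_headgroups": plan.n_lining_headgroups,
        "frames": (first, last),
        "center_xy": tuple(np.asarray(center, dtype=float)),
        "water_mol_ids": list(chosen),
    })
    meta["planted"] = planted
    return Trajectory(new_frames, frame_interval=traj.frame_interval,
                      metadata=meta)


# ---------------------------------------------------------------------------
# auxiliary synthetic systems

def solvent_slab_from_potential(n_molecules: int, box, potential,
                                temperature: float = 310.0, seed: int = 0,
                                n_frames: int = 1,
                                frame_interval: float = 100.0) -> Trajectory:
    """Water-only frames with z sampled from the Boltzmann weight of a given
    1-D potential U(z) in kJ/mol.

    The sampling density is exp(-U(z)/RT), so Boltzmann inversion of the
    measured density profile must recover U up to its bulk offset; this is
    the ground-truth companion of the free-energy analysis.
    """
    box = np.asarray(box, dtype=float)
    rt = R_GAS * temperature
    zg = np.linspace(0.0, box[2], 4001)
    wmax = float(np.max(np.exp(-np.asarray(potential(zg)) / rt)))
    children = np.random.SeedSequence([seed, 4242]).spawn(n_frames)
    frames = []
    topo = None
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        z = np.empty(n_molecules)
        filled = 0
        while filled < n_molecules:
            m = 2 * (n_molecules - filled) + 64
            cand = rng.uniform(0.0, box[2], m)
            w = np.exp(-np.asarray(potential(cand)) / rt) / wmax
            cand = cand[rng.random(m) < w][: n_molecules - filled]
            z[filled:filled + cand.size] = cand
            filled += cand.size
        o = np.stack([rng.uniform(0, box[0], n_molecules),
                      rng.uniform(0, box[1], n_molecules), z], axis=1)
        dip = _unit_from_cos_az(rng.uniform(-1, 1, n_molecules),
                                rng.uniform(0, 2 * np.pi, n_molecules))
        p_perp, _ = _perp_frame(dip)
        ha = _OH_BOND * (math.cos(_HOH_HALF) * dip + math.sin(_HOH_HALF) * p_perp)
        hb = _OH_BOND * (math.cos(_HOH_HALF) * dip - math.sin(_HOH_HALF) * p_perp)
        n = n_molecules
        pos = np.empty((3 * n, 3))
        pos[0::3] = o
        pos[1::3] = o + ha
        pos[2::3] = o + hb
        if topo is None:
            topo = Topology(
                atom_ids=np.arange(3 * n),
                mol_ids=np.repeat(np.arange(n), 3),
                mol_kinds=np.full(3 * n, int(MoleculeKind.WATER)),
                atom_names=np.tile(np.array(["OW", "HW1", "HW2"],
                                            dtype="<U5"), n),
                roles=np.tile(np.array([int(AtomRole.WATER_O),
                                        int(AtomRole.WATER_H),
                                        int(AtomRole.WATER_H)]), n),
                tail_chain=np.full(3 * n, -1),
                tail_pos=np.full(3 * n, -1),
                masses=np.tile(np.array([_M_O, _M_H, _M_H]), n),
            )
        frames.append(BilayerFrame(topo, np.mod(pos, box), box,
                                   time=k * frame_interval))
    return Trajectory(frames, frame_interval=frame_interval)


def isotropic_dmso_box(n_molecules: int, box, seed: int = 0) -> BilayerFrame:
    """DMSO-only configuration with uniform positions and isotropic O->S
    dipole orientations (the 90-degree baseline of the orientation
    analysis)."""
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9090]))
    n = n_molecules
    s = np.stack([rng.uniform(0, box[0], n), rng.uniform(0, box[1], n),
                  rng.uniform(0, box[2], n)], axis=1)
    dip = _unit_from_cos_az(rng.uniform(-1, 1, n),
                            rng.uniform(0, 2 * np.pi, n))
    p_perp, _ = _perp_frame(dip)
    pos = np.empty((4 * n, 3))
    pos[0::4] = s
    pos[1::4] = s - _OS_BOND * dip
    pos[2::4] = s + 0.18 * (0.5 * dip + 0.866 * p_perp)
    pos[3::4] = s + 0.18 * (0.5 * dip - 0.866 * p_perp)
    topo = Topology(
        atom_ids=np.arange(4 * n),
        mol_ids=np.repeat(np.arange(n), 4),
        mol_kinds=np.full(4 * n, int(MoleculeKind.DMSO)),
        atom_names=np.tile(np.array(["S", "O", "C1", "C2"], dtype="<U5"), n),
        roles=np.tile(np.array([int(AtomRole.DMSO_S), int(AtomRole.DMSO_O),
                                int(AtomRole.DMSO_C), int(AtomRole.DMSO_C)]), n),
        tail_chain=np.full(4 * n, -1),
        tail_pos=np.full(4 * n, -1),
        masses=np.tile(np.array([_M_S, _M_O, _M_CH3, _M_CH3]), n),
    )
    return BilayerFrame(topo, np.mod(pos, box), box)
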