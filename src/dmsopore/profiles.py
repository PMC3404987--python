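"""Mass-density profiles, Boltzmann-inversion free energy, and structural
summaries of a bilayer trajectory.

The density profile rho(z) of a component (water, DOPC, Chol, DMSO) is the
frame-averaged histogram of atomic masses along the bilayer normal divided by
the bin volume.  On the scaled coordinate Z' the phosphate-density maxima of
the two leaflets sit at exactly +-1.  Boltzmann inversion turns a density
profile into a potential of mean force,

    dG(z) = -RT ln(rho(z) / rho_0),

with rho_0 the mean density over the designated bulk region (|Z'| > 1.5 by
default).  Bins with zero density are flagged unbounded, never imputed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model_io import AtomRole, MoleculeKind, Trajectory, assign_leaflets

__all__ = [
    "DensityProfile",
    "FreeEnergyProfile",
    "MembraneSummary",
    "MembraneScaling",
    "mass_density_profile",
    "membrane_scaling",
    "scale_coordinate",
    "pmf_from_density",
    "pp_distance",
    "membrane_summary",
    "relative_change",
]

R_GAS = 8.314e-3  # kJ mol^-1 K^-1
_U_PER_NM3_TO_KG_M3 = 1.66053906660
DEFAULT_BULK_ZSCALED = 1.5

_COMPONENT_KIND = {
    "WATER": MoleculeKind.WATER,
    "DOPC": MoleculeKind.DOPC,
    "CHOL": MoleculeKind.CHOL,
    "DMSO": MoleculeKind.DMSO,
}


class ScalingError(ValueError):
    """The phosphate profile has no two separated maxima (membrane not
    intact), so Z' is undefined."""


@dataclasses.dataclass
class DensityProfile:
    """Binned mass density of one component along z."""

    component: str
    edges: np.ndarray  # raw z bin edges, nm
    rho: np.ndarray  # kg m^-3
    n_frames_averaged: int
    z_scaled: np.ndarray | None = None  # Z' at bin centers
    rho_bulk: float | None = None  # kg m^-3

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclasses.dataclass
class FreeEnergyProfile:
    """Boltzmann-inverted profile; NaN marks unbounded (rho = 0) bins."""

    bin_centers: np.ndarray  # raw z, nm
    delta_G: np.ndarray  # kJ/mol, NaN where unbounded
    temperature: float  # K
    z_scaled: np.ndarray | None = None
    n_unbounded: int = 0

    @property
    def barrier_height(self) -> float:
        """Max dG over finite bins (the permeation barrier)."""
        finite = self.delta_G[np.isfinite(self.delta_G)]
        return float(np.max(finite)) if finite.size else float("nan")


@dataclasses.dataclass
class MembraneSummary:
    """One row of structural observables for a condition."""

    area: float  # nm^2
    pp_distance: float  # nm
    mean_scd: float  # <-S_CD>
    tail_tilt_deg: float
    chol_tilt_deg: float


@dataclasses.dataclass
class MembraneScaling:
    """Piecewise-linear map z -> Z' anchored on the phosphate maxima."""

    z_mid: float
    h_upper: float  # z_P(upper) - z_mid, > 0
    h_lower: float  # z_mid - z_P(lower), > 0

    def to_scaled(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        up = z >= self.z_mid
        out = np.empty_like(z)
        out[up] = (z[up] - self.z_mid) / self.h_upper
        out[~up] = (z[~up] - self.z_mid) / self.h_lower
        return out


def _component_mask(topology, component: str) -> np.ndarray:
    try:
        kind = _COMPONENT_KIND[component.upper()]
    except KeyError:
        raise ValueError(f"unknown component {component!r}; expected one of "
                         f"{sorted(_COMPONENT_KIND)}")
    return topology.mol_kinds == kind


def mass_density_profile(traj: Trajectory, component: str,
                         bin_width: float = 0.05) -> DensityProfile:
    """Frame-averaged mass density rho(z) of one component, kg m^-3.

    Bins are uniform in raw z over [0, Lz]; each frame's histogram of atomic
    masses is divided by the slab volume Lx*Ly*bin_width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    t = traj.topology
    mask = _component_mask(t, component)
    lz = float(traj.frames[0].box[2])
    nbins = max(int(round(lz / bin_width)), 1)
    edges = np.linspace(0.0, lz, nbins + 1)
    acc = np.zeros(nbins)
    for f in traj.frames:
        if abs(float(f.box[2]) - lz) > 1e-9:
            raise ValueError("frames disagree on box height; rebin per group")
        hist, _ = np.histogram(f.positions[mask, 2], bins=edges,
                               weights=t.masses[mask])
        vol = f.area * (lz / nbins)  # nm^3 per bin
        acc += hist / vol
    rho = acc / traj.n_frames * _U_PER_NM3_TO_KG_M3
    return DensityProfile(component=component.upper(), edges=edges, rho=rho,
                          n_frames_averaged=traj.n_frames)


def membrane_scaling(traj: Trajectory, bin_width: float = 0.05) -> MembraneScaling:
    """Derive the z -> Z' map from the phosphate-marker density maxima.

    The midplane is the trajectory-mean phosphate z; each leaflet is scaled
    by the distance from the midplane to its own phosphate-density maximum,
    so the maxima land at exactly +-1.
    """
    t = traj.topology
    p_mask = t.roles == AtomRole.PHOSPHATE_MARKER
    if not np.any(p_mask):
        raise ScalingError("no phosphate markers; Z' scaling undefined")
    z_all = np.concatenate([f.positions[p_mask, 2] for f in traj.frames])
    z_mid = float(np.mean(z_all))
    lz = float(traj.frames[0].box[2])
    nbins = max(int(round(lz / bin_width)), 1)
    edges = np.linspace(0.0, lz, nbins + 1)
    hist, _ = np.histogram(z_all, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    up = centers >= z_mid
    if not (np.any(hist[up] > 0) and np.any(hist[~up] > 0)):
        raise ScalingError("phosphate density lacks two separated maxima; "
                           "membrane not intact")
    z_up = float(centers[up][np.argmax(hist[up])])
    z_lo = float(centers[~up][np.argmax(hist[~up])])
    h_upper, h_lower = z_up - z_mid, z_mid - z_lo
    if h_upper <= 0 or h_lower <= 0:
        raise ScalingError("phosphate maxima collapse onto the midplane")
    return MembraneScaling(z_mid=z_mid, h_upper=h_upper, h_lower=h_lower)


def scale_coordinate(profile: DensityProfile, traj: Trajectory,
                     bulk_zscaled: float = DEFAULT_BULK_ZSCALED,
                     scaling: MembraneScaling | None = None) -> DensityProfile:
    """Populate Z' on a profile and evaluate the bulk density rho_0.

    rho_0 is the mean density over |Z'| > ``bulk_zscaled``; it is left None
    (undefined) when the component has no mass there.
    """
    if scaling is None:
        scaling = membrane_scaling(traj, bin_width=profile.bin_width)
    z_scaled = scaling.to_scaled(profile.bin_centers)
    bulk = np.abs(z_scaled) > bulk_zscaled
    rho_bulk = None
    if np.any(bulk):
        mean = float(np.mean(profile.rho[bulk]))
        if mean > 0:
            rho_bulk = mean
    return DensityProfile(component=profile.component, edges=profile.edges,
                          rho=profile.rho,
                          n_frames_averaged=profile.n_frames_averaged,
                          z_scaled=z_scaled, rho_bulk=rho_bulk)


def pmf_from_density(profile: DensityProfile, temperature: float = 310.0,
                     rho0: float | None = None,
                     bulk_mask: np.ndarray | None = None) -> FreeEnergyProfile:
    """Boltzmann inversion dG(z) = -RT ln(rho/rho_0), kJ/mol.

    ``rho0`` defaults to the profile's bulk density; ``bulk_mask`` (raw-z
    bins considered bulk) fixes the gauge so the bulk-average of dG is zero.
    Zero-density bins come back NaN and are counted, never given finite
    values.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if rho0 is None:
        rho0 = profile.rho_bulk
    if rho0 is None or rho0 <= 0:
        raise ValueError(
            "bulk density rho_0 undefined or non-positive; run "
            "scale_coordinate first (bulk region |Z'| > 1.5 by default) or "
            "pass rho0 explicitly")
    rt = R_GAS * temperature
    rho = profile.rho
    with np.errstate(divide="ignore"):
        dg = np.where(rho > 0, -rt * np.log(np.where(rho > 0, rho, 1.0) / rho0),
                      np.nan)
    if bulk_mask is None and profile.z_scaled is not None:
        bulk_mask = np.abs(profile.z_scaled) > DEFAULT_BULK_ZSCALED
    if bulk_mask is not None and np.any(bulk_mask & np.isfinite(dg)):
        dg = dg - np.nanmean(dg[bulk_mask])
    return FreeEnergyProfile(bin_centers=profile.bin_centers, delta_G=dg,
                             temperature=temperature,
                             z_scaled=profile.z_scaled,
                             n_unbounded=int(np.sum(~np.isfinite(dg))))


def pp_distance(traj: Trajectory) -> float:
    """Frame-averaged |mean z(upper phosphates) - mean z(lower phosphates)|,
    nm (the membrane thickness proxy)."""
    t = traj.topology
    p_mask = t.roles == AtomRole.PHOSPHATE_MARKER
    vals = []
    for f in traj.frames:
        la = assign_leaflets(f)
        leaf_of = la.as_dict()
        sides = np.array([leaf_of.get(int(m), 0) for m in t.mol_ids[p_mask]])
        z = f.positions[p_mask, 2]
        if not (np.any(sides > 0) and np.any(sides < 0)):
            raise ValueError("a leaflet has no phosphates; P-P distance undefined")
        vals.append(abs(float(np.mean(z[sides > 0]) - np.mean(z[sides < 0]))))
    return float(np.mean(vals))


def membrane_summary(traj: Trajectory) -> MembraneSummary:
    """The five structural observables for one condition: area, P-P
    distance, <-S_CD>, tail tilt and Chol tilt."""
    from .ordering import scd_profile, tilt_angles

    area = float(np.mean([f.area for f in traj.frames]))
    order = scd_profile(traj)
    tilt = tilt_angles(traj)
    return MembraneSummary(area=area, pp_distance=pp_distance(traj),
                           mean_scd=order.mean_minus_scd,
                           tail_tilt_deg=tilt.tail_tilt_deg,
                           chol_tilt_deg=tilt.chol_tilt_deg)


def relative_change(summary_a, summary_b, field: str) -> float:
    """Signed percent change 100*(b - a)/a of one summary field."""
    a = getattr(summary_a, field) if hasattr(summary_a, field) else summary_a[field]
    b = getattr(summary_b, field) if hasattr(summary_b, field) else summary_b[field]
    if a == 0:
        raise ValueError(f"relative change undefined: field {field!r} is 0 "
                         "in the reference")
    return 100.0 * (b - a) / a
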