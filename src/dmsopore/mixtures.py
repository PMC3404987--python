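"""DMSO/water composition conversions between volume and mole percent.

Ideal-volume mixing: a v vol% mixture contributes n_d = v rho_d / M_d moles
of DMSO and n_w = (100 - v) rho_w / M_w moles of water per 100 mL, giving
mol% = 100 n_d / (n_d + n_w).  Default constants (rho in g/mL, M in g/mol)
reproduce the standard printed pairs 10->2.74, 20->5.97, 30->9.79 and
40->14.5 mol% within 0.05 mol%.
"""

from __future__ import annotations

import dataclasses

__all__ = ["MixtureConstants", "MixtureSpec", "vol_to_mol", "mol_to_vol"]


@dataclasses.dataclass(frozen=True)
class MixtureConstants:
    density_dmso: float = 1.10  # g/mL
    density_water: float = 1.00  # g/mL
    molar_mass_dmso: float = 78.13  # g/mol
    molar_mass_water: float = 18.02  # g/mol

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")

    @property
    def a(self) -> float:
        """Molar volume concentration of DMSO, mol/mL."""
        return self.density_dmso / self.molar_mass_dmso

    @property
    def b(self) -> float:
        """Molar volume concentration of water, mol/mL."""
        return self.density_water / self.molar_mass_water


DEFAULT_CONSTANTS = MixtureConstants()


def _check_percent(x: float, name: str) -> None:
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"{name} must be in [0, 100], got {x}")


def vol_to_mol(vol_percent: float,
               constants: MixtureConstants = DEFAULT_CONSTANTS) -> float:
    """Mole percent of DMSO in the solvent for a given volume percent."""
    _check_percent(vol_percent, "vol_percent")
    n_d = vol_percent * constants.a
    n_w = (100.0 - vol_percent) * constants.b
    return 100.0 * n_d / (n_d + n_w)


def mol_to_vol(mol_percent: float,
               constants: MixtureConstants = DEFAULT_CONSTANTS) -> float:
    """Exact algebraic inverse of :func:`vol_to_mol`."""
    _check_percent(mol_percent, "mol_percent")
    a, b = constants.a, constants.b
    return 100.0 * mol_percent * b / (a * (100.0 - mol_percent)
                                      + b * mol_percent)


@dataclasses.dataclass
class MixtureSpec:
    """A DMSO/water composition in both units, with its constants."""

    dmso_vol_percent: float
    dmso_mol_percent: float
    constants: MixtureConstants = DEFAULT_CONSTANTS

    @classmethod
    def from_vol(cls, vol_percent: float,
                 constants: MixtureConstants = DEFAULT_CONSTANTS):
        return cls(vol_percent, vol_to_mol(vol_percent, constants), constants)

    @classmethod
    def from_mol(cls, mol_percent: float,
                 constants: MixtureConstants = DEFAULT_CONSTANTS):
        return cls(mol_to_vol(mol_percent, constants), mol_percent, constants)
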