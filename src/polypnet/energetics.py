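"""Cellular energy allocation: standard curves, Ea, Ec and CEA.

Energy available (Ea, J) converts macromolecule masses through combustion
enthalpies (defaults 17.5 kJ/g carbohydrate, 39.5 kJ/g lipid, 24 kJ/g
protein).  Energy consumption (Ec, J h^-1) converts the kinetic slope of
the INT-formazan electron-transport-system assay into an oxygen
consumption rate (2 formazan per O2) and then into heat through the
oxyenthalpic equivalent 484 kJ per mol O2.  CEA = Ea / Ec.  All conversion
constants live in :class:`EnergyConstants` and can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnergyConstants",
    "StandardCurve",
    "EnergyBudget",
    "fit_standard_curve",
    "quantify",
    "energy_available",
    "energy_consumption",
    "cea",
    "normalize_energy",
]


@dataclass(frozen=True)
class EnergyConstants:
    """Conversion constants of the cellular-energy-allocation calculus."""

    carbohydrate_j_per_g: float = 17500.0
    lipid_j_per_g: float = 39500.0
    protein_j_per_g: float = 24000.0
    o2_j_per_umol: float = 0.484  # 484 kJ mol^-1 O2
    formazan_per_o2: float = 2.0
    int_epsilon_au_l_per_umol_cm: float = 0.0159  # 15,900 L mol^-1 cm^-1


DEFAULT_CONSTANTS = EnergyConstants()


@dataclass(frozen=True)
class StandardCurve:
    concentrations: np.ndarray  # mg mL^-1
    absorbances: np.ndarray  # AU
    slope: float  # AU per mg mL^-1
    intercept: float  # AU
    r_squared: float


@dataclass
class EnergyBudget:
    """Per-sample energy budget with its normalisation basis."""

    carbohydrate_mg: float
    lipid_mg: float
    protein_mg: float
    ea_joule: float
    ec_joule_per_h: float
    cea: float
    basis: str = "raw"  # raw | per_cm2 | per_polyp
    basis_value: float = 1.0


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """Ordinary least-squares line absorbance = slope*conc + intercept."""
    conc = np.asarray(concentrations, dtype=float)
    ab = np.asarray(absorbances, dtype=float)
    if conc.size != ab.size:
        raise ValueError("concentrations and absorbances must have equal length")
    if conc.size < 2:
        raise ValueError("at least two standards are required")
    if np.ptp(conc) == 0:
        raise ValueError("standard concentrations are all identical (degenerate design)")
    fit = stats.linregress(conc, ab)
    return StandardCurve(
        concentrations=conc,
        absorbances=ab,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def quantify(curve: StandardCurve, absorbance: float, dilution_factor: float = 1.0) -> float:
    """Invert a standard curve: concentration (mg mL^-1) of an unknown well."""
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero; cannot invert")
    conc = dilution_factor * (absorbance - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn("negative concentration clamped to 0", stacklevel=2)
        conc = 0.0
    return float(conc)


def energy_available(
    carbohydrate_g: float,
    lipid_g: float,
    protein_g: float,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Ea (J) from macromolecule masses in grams."""
    if min(carbohydrate_g, lipid_g, protein_g) < 0:
        raise ValueError("masses must be non-negative")
    return (
        constants.carbohydrate_j_per_g * carbohydrate_g
        + constants.lipid_j_per_g * lipid_g
        + constants.protein_j_per_g * protein_g
    )


def energy_consumption(
    kinetic_slope: float,
    reaction_volume_l: float,
    path_cm: float = 1.0,
    epsilon: float | None = None,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Ec (J h^-1) from the ETS assay kinetic slope (AU min^-1).

    Beer--Lambert converts the slope into a formazan production rate,
    stoichiometry (2 formazan : 1 O2) into an oxygen consumption rate, and
    the oxyenthalpic equivalent into heat per hour.  A negative slope
    signals mis-ordered kinetic reads and raises.
    """
    if kinetic_slope < 0:
        raise ValueError("kinetic slope must be non-negative (check read order)")
    if reaction_volume_l <= 0 or path_cm <= 0:
        raise ValueError("reaction volume and path length must be positive")
    eps = constants.int_epsilon_au_l_per_umol_cm if epsilon is None else epsilon
    if eps <= 0:
        raise ValueError("molar absorptivity must be positive")
    formazan_umol_per_min = kinetic_slope * reaction_volume_l / (eps * path_cm)
    o2_umol_per_min = formazan_umol_per_min / constants.formazan_per_o2
    return o2_umol_per_min * 60.0 * constants.o2_j_per_umol


def cea(ea_joule: float, ec_joule_per_h: float) -> float:
    """Cellular energy allocation: Ea / Ec."""
    if ec_joule_per_h <= 0:
        raise ValueError("Ec must be positive to form CEA")
    return ea_joule / ec_joule_per_h


def normalize_energy(value: float, basis: str, basis_value: float) -> float:
    """Normalise an energy value per cm^2 of surface or per polyp."""
    if basis not in ("area_cm2", "polyps"):
        raise ValueError(f"unknown normalisation basis {basis!r}")
    if basis_value <= 0:
        raise ValueError("basis value must be positive")
    return value / basis_value
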