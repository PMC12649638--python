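"""Physiological calculators: symbiont density, chlorophyll, caspase-3.

Chlorophyll a and c2 (ug mL^-1 of acetone extract) follow the standard
dinoflagellate two-wavelength linear equations

    chl_a  = 11.43 * OD663 - 0.64 * OD630
    chl_c2 = 27.09 * OD630 - 3.63 * OD663

with coefficients exposed as module constants so an alternative calibration
(e.g. a different acetone fraction) can be substituted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "CHL_A_COEFFS",
    "CHL_C2_COEFFS",
    "symbiont_density",
    "chlorophyll_per_cell",
    "caspase_activation",
    "derive_physiology",
]

# (coefficient on OD663, coefficient on OD630), ug mL^-1 per absorbance unit
CHL_A_COEFFS: tuple[float, float] = (11.43, -0.64)
CHL_C2_COEFFS: tuple[float, float] = (-3.63, 27.09)


def symbiont_density(total_cells: float, surface_area: float) -> float:
    """Symbiont cells per cm^2 of coral surface."""
    if surface_area <= 0:
        raise ValueError("surface_area must be positive")
    if total_cells < 0:
        raise ValueError("total_cells must be non-negative")
    return total_cells / surface_area


def chlorophyll_per_cell(
    od630: float,
    od663: float,
    extract_volume: float,
    cell_count: float,
    chl_a_coeffs: tuple[float, float] = CHL_A_COEFFS,
    chl_c2_coeffs: tuple[float, float] = CHL_C2_COEFFS,
) -> float:
    """Total chlorophyll a+c2 per symbiont cell (pg cell^-1).

    ``extract_volume`` is the acetone extract volume in mL; ``cell_count``
    the number of cells the extract derives from.  Near-blank readings can
    push either linear equation negative; such pigment estimates are clamped
    to zero with a warning rather than aborting the pipeline.
    """
    if cell_count <= 0:
        raise ValueError("cell_count must be positive")
    if extract_volume <= 0:
        raise ValueError("extract_volume must be positive")
    chl_a = chl_a_coeffs[0] * od663 + chl_a_coeffs[1] * od630
    chl_c2 = chl_c2_coeffs[0] * od663 + chl_c2_coeffs[1] * od630
    if chl_a < 0 or chl_c2 < 0:
        warnings.warn(
            "negative chlorophyll estimate clamped to 0 (near-blank reading)",
            stacklevel=2,
        )
        chl_a = max(chl_a, 0.0)
        chl_c2 = max(chl_c2, 0.0)
    total_ug = (chl_a + chl_c2) * extract_volume
    return total_ug * 1e6 / cell_count  # ug -> pg


def caspase_activation(feeding_a405, control_a405) -> float:
    """Caspase-3 activation level: mean feeding A405 / mean control A405.

    A ratio below 1 indicates suppressed apoptosis in the feeding group.
    """
    feeding = np.asarray(feeding_a405, dtype=float)
    control = np.asarray(control_a405, dtype=float)
    if feeding.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError("control mean A405 must be positive")
    return float(feeding.mean() / control_mean)


def derive_physiology(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive reported quantities from a raw per-colony physiology table.

    Expects columns ``colony, group, symbiont_count, surface_area_cm2,
    od630, od663, extract_volume_ml``.  Returns a table with
    ``symbiont_density_cells_cm2`` and ``chlorophyll_pg_cell`` added;
    passthrough columns (e.g. T-AOC, MDA) are kept untouched.
    """
    required = {"colony", "group", "symbiont_count", "surface_area_cm2",
                "od630", "od663", "extract_volume_ml"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"physiology table missing columns: {sorted(missing)}")
    out = raw.copy()
    out["symbiont_density_cells_cm2"] = [
        symbiont_density(c, a) for c, a in zip(raw["symbiont_count"], raw["surface_area_cm2"])
    ]
    out["chlorophyll_pg_cell"] = [
        chlorophyll_per_cell(od630, od663, vol, cells)
        for od630, od663, vol, cells in zip(
            raw["od630"], raw["od663"], raw["extract_volume_ml"], raw["symbiont_count"]
        )
    ]
    return out
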