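"""Unit conversions between the spatial layer and the FBA layer.

The spatial fields are kept in mol l^-1 (M), lengths in m and times in s,
while the metabolic layer speaks the flux-balance community's customary
mmol gDwt^-1 hr^-1.  All conversions between the two unit systems live
here so that no kernel hand-rolls its own factors.
"""

from __future__ import annotations

#: litres per cubic metre
L_PER_M3 = 1e3
#: seconds per hour
S_PER_HR = 3600.0
#: mol per mmol
MOL_PER_MMOL = 1e-3


def cell_density_g_per_l(m_cell: float, v_cell: float) -> float:
    """Dry-mass density of packed cells, g l^-1, from single-cell mass (g)
    and volume (m^3)."""
    return m_cell / (v_cell * L_PER_M3)


def specific_to_volumetric(v_specific: float, m_cell: float, v_cell: float) -> float:
    """Convert a specific rate (mmol gDwt^-1 hr^-1) to a volumetric
    concentration rate (mol l^-1 s^-1) for cells at volume fraction 1.

    Multiply by the local volume fraction rho to get the actual local rate.
    """
    return v_specific * MOL_PER_MMOL / S_PER_HR * cell_density_g_per_l(m_cell, v_cell)


def availability_factor(m_cell: float, v_cell: float, dtau: float) -> float:
    """Factor turning a concentration (M) into the maximum specific uptake
    rate (mmol gDwt^-1 hr^-1) sustainable over one sub-step of length dtau.

    availability = phi * V_cell / (m_cell * dtau), expressed per hour/mmol.
    """
    v_cell_l = v_cell * L_PER_M3
    return v_cell_l / (m_cell * dtau) / MOL_PER_MMOL * S_PER_HR


def flux_to_concentration_factor(m_cell: float, v_cell: float, dtau: float) -> float:
    """Factor turning a specific exchange flux (mmol gDwt^-1 hr^-1) times the
    local volume fraction into a concentration change (M) over one sub-step."""
    return MOL_PER_MMOL / S_PER_HR * cell_density_g_per_l(m_cell, v_cell) * dtau
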