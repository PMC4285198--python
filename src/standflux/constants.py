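"""Physical constants and stand/site defaults.

Defaults describe a mature rubber-tree (*Hevea brasiliensis*) plantation in a
tropical sub-humid climate: 2.5 m x 7.0 m planting spacing (571 trees ha-1),
mean sapwood area 1.97e-2 m2 per tree at probe height, and a radial-profile
reduction coefficient of 0.874 applied to outer-ring sap flux density.
"""

from __future__ import annotations

from dataclasses import dataclass

# --- Penman-Monteith inversion constants (well-coupled canopy) ---
GAMMA_PA_K = 66.0        # psychrometric constant, Pa K-1
LAMBDA_J_KG = 2.45e6     # latent heat of vaporization, J kg-1
CP_J_KG_K = 1013.0       # specific heat of dry air, J kg-1 K-1
RHO_KG_M3 = 1.204        # density of dry air, kg m-3

# --- FAO-56 radiation constants ---
SOLAR_CONSTANT_MJ_M2_MIN = 0.0820
STEFAN_BOLTZMANN_MJ_K4_M2_DAY = 4.903e-9
REFERENCE_ALBEDO = 0.23

# --- transient thermal dissipation (TTD) sap-flow calibration ---
# Js (kg m-2 h-1) = 12.95 x Ka x 10^2, non-species-specific calibration
TTD_CALIBRATION_KG_M2_H = 12.95 * 1.0e2

# --- stand geometry defaults ---
DEFAULT_RADIAL_COEFF = 0.874
DEFAULT_SAPWOOD_AREA_M2 = 1.97e-2
DEFAULT_ROW_SPACING_M = (2.5, 7.0)


@dataclass(frozen=True)
class Site:
    """Geographic constants needed by the FAO-56 radiation terms.

    Defaults correspond to a low-latitude lowland site in northeast Thailand.
    """

    latitude_deg: float = 15.27
    elevation_m: float = 150.0
    albedo: float = REFERENCE_ALBEDO

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude_deg}")
        if not 0.0 < self.albedo < 1.0:
            raise ValueError(f"albedo must be in (0, 1): {self.albedo}")
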