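"""Physical constants and unit conversions used across the package.

Conventions: radial kernel distances in nm, cell-scale positions in µm,
doses in Gy, masses in g unless a name says otherwise.
"""

import math

GOLD_DENSITY_G_CM3 = 19.32
WATER_DENSITY_G_CM3 = 1.0

NM3_TO_CM3 = 1e-21
NM_PER_UM = 1000.0
G_TO_KG = 1e-3


def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius**3


def gnp_gold_mass_g(diameter_nm: float) -> float:
    """Mass of a solid gold sphere of the given diameter, in grams.

    A 10 nm GNP weighs ~1.01e-17 g.
    """
    if diameter_nm <= 0:
        raise ValueError(f"GNP diameter must be positive, got {diameter_nm} nm")
    volume_cm3 = math.pi / 6.0 * diameter_nm**3 * NM3_TO_CM3
    return volume_cm3 * GOLD_DENSITY_G_CM3
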