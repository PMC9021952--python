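"""Unit conversions used throughout the package.

All internal computation is metric: lengths in meters, areas in m²,
densities per km². These helpers exist for reporting in customary units
(the sampling frame's defaults are usually quoted in miles/feet/acres).
"""

M_PER_FOOT = 0.3048
M_PER_MILE = 1609.344
M2_PER_ACRE = 4046.8564224
M2_PER_KM2 = 1_000_000.0

#: Default lattice spacing, meters (one tenth of a statute mile).
DEFAULT_SPACING_M = 161.0

#: Default centroid-augmentation area threshold, m² (≈16.6 acres).
DEFAULT_AREA_THRESHOLD_M2 = 67_261.0


def meters_to_feet(m: float) -> float:
    return m / M_PER_FOOT


def meters_to_miles(m: float) -> float:
    return m / M_PER_MILE


def m2_to_acres(m2: float) -> float:
    return m2 / M2_PER_ACRE


def m2_to_km2(m2: float) -> float:
    return m2 / M2_PER_KM2
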