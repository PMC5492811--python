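"""Vegetation indices from a synthetic canopy spectrum.

Builds pure-vegetation spectra for a healthy (chlorophyll 45 ug/cm^2,
LAI 3.5) and a stressed (25 ug/cm^2, LAI 1.5) potato canopy on the UAV
band set, then prints a few indices.  Chlorophyll-sensitive indices
(TCARI/OSAVI, CI_g, MTCI) and structure-sensitive ones (NDVI, OSAVI,
MCARI2) separate the two canopies in different ways; REP is the red
edge position in nm.
"""

from canopytrait import (
    SoilLine,
    compute_index,
    uav_band_set,
    vegetation_reflectance,
)

band_set = uav_band_set()
healthy = vegetation_reflectance(leaf_chl=45.0, lai=3.5, band_set=band_set)
stressed = vegetation_reflectance(leaf_chl=25.0, lai=1.5, band_set=band_set)

soil = SoilLine(1.3)  # bare-soil NIR/red reflectance ratio for WDVI
names = ["NDVI", "OSAVI", "WDVI", "TCARI_OSAVI", "CI_g", "MCARI2", "MTCI", "REP"]

print(f"{'index':<14}{'healthy':>10}{'stressed':>10}")
for name in names:
    h = compute_index(healthy, name, soil_line=soil)
    s = compute_index(stressed, name, soil_line=soil)
    print(f"{name:<14}{h:>10.3f}{s:>10.3f}")
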