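"""Generate a synthetic city and inspect its planted social geography.

Builds an "Aarhus-like" city — income and PM2.5 both highest in the centre —
and prints the land-cover composition, total population and the zone-level
income range, then writes the city to ./scratch_city/ in the pipeline's
GeoTIFF/GeoJSON/CSV layout.
"""

import numpy as np

import greenequity as ge

cfg = ge.CityConfig.aarhus_like(seed=1, extent_m=6000.0, n_zones=25, n_buildings=500)
city = ge.generate_city(cfg)

total = city.landcover.classes.size
print("land-cover composition (fraction of 5 m cells):")
for cls in ge.LandClass:
    frac = np.count_nonzero(city.landcover.classes == int(cls)) / total
    print(f"  {cls.name.lower():9s} {frac:6.3f}")
print(f"buildings: {len(city.buildings)}, residents: {sum(b.population for b in city.buildings):,.0f}")
inc = city.zone_table.median_income
print(f"zone median income range: {inc.min():,.0f} - {inc.max():,.0f}")
print(f"planted income-PM2.5 association sign: {city.truth['income_pm25_corr_sign']:+d}"
      " (+1 means richer zones sit in worse air)")

ge.write_city(city, "scratch_city")
print("wrote city files to ./scratch_city/")
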