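"""From tree cover to PM2.5: the meta-model delta/downscaling chain.

Evaluates the two shipped city meta-models, then runs the full chain on a
synthetic city: woodland fraction per 3 km cell -> percentage PM2.5 change
-> absolute delta against the coarse baseline -> bilinear downscale to 1 km
-> added to the fine baseline surface.
"""

import numpy as np

import greenequity as ge

for model in (ge.AARHUS, ge.PARIS):
    print(f"{model.name}: pcPM(0) = {ge.pcpm(model, 0.0):+.4f}%  "
          f"pcPM(0.3) = {ge.pcpm(model, 0.3):+.4f}%  pcPM(1) = {ge.pcpm(model, 1.0):+.4f}%")
print("(negative percentages: woodland removes PM2.5 by deposition)")

city = ge.generate_city(ge.CityConfig.aarhus_like(seed=1, extent_m=6000.0, n_zones=25, n_buildings=500))
greened = ge.apply_330(city.landcover, city.buildings, city.zones, ge.GreeningParams(seed=1))
surfaces = ge.scenario_surfaces(
    ge.AARHUS, city.landcover, greened.landcover_scenario,
    city.coarse_pm25.grid, city.coarse_pm25, city.fine_pm25,
)

diff = surfaces.pm25_scenario_fine.values - surfaces.pm25_current_fine.values
print(f"fine-surface mean PM2.5: current {surfaces.pm25_current_fine.values.mean():.3f}, "
      f"scenario {surfaces.pm25_scenario_fine.values.mean():.3f} ug/m3")
print(f"greening changes concentrations by {diff.min():.4f} to {diff.max():.4f} ug/m3 per 1 km cell")
assert np.all(diff <= 0), "linear model: more trees can only reduce concentrations"
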