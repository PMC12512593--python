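"""Tree-cover -> PM2.5 meta-models and the delta/downscaling chain.

A meta-model is a reduced-form regression emulating a full atmospheric
chemistry transport model (EMEP-WRF): it maps the woodland fraction of a
coarse (3 km) grid cell to the percentage change in PM2.5 concentration
attributable to deposition on leaf surfaces,

    pcPM(w) = c2*w^2 + c1*w + c0        (percent, w = woodfrac in [0, 1]).

Two city-specific models ship with the package:

* Aarhus:  pcPM = -3.9134*w - 0.1636          (linear)
* Paris:   pcPM = 6.0425*w^2 - 8.9865*w - 0.8939   (quadratic; its vertex at
  w = 8.9865 / (2*6.0425) ~ 0.7436 is the minimum on [0, 1], so the marginal
  benefit of extra woodland declines and eventually reverses sign there)

Both predict pcPM < 0 everywhere on [0, 1]: modelled greening never worsens
air quality.  Percentage changes are converted to absolute deltas against the
coarse modelled baseline, bilinearly downscaled to the fine (1 km) grid, and
added to an independent fine-resolution baseline surface — the delta
(bias-correction) method familiar from climate scenario work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .raster_core import (
    ConcentrationRaster,
    GridSpec,
    LandClass,
    LandCoverRaster,
    bilinear_resample,
    class_fraction,
    require_aligned,
)


@dataclass(frozen=True)
class MetaModel:
    """Quadratic meta-model pcPM(w) = c2*w^2 + c1*w + c0 (percent)."""

    c2: float
    c1: float
    c0: float
    name: str = "custom"

    def __post_init__(self) -> None:
        # the models this package is meant for predict a concentration
        # *reduction* for every admissible woodland fraction
        w = np.linspace(0.0, 1.0, 1001)
        pc = self.c2 * w * w + self.c1 * w + self.c0
        if np.any(pc > 0):
            raise ConfigurationError(
                f"meta-model {self.name!r} predicts a PM2.5 increase "
                f"(pcPM > 0) for some woodfrac in [0, 1]"
            )

    def __call__(self, woodfrac):
        return pcpm(self, woodfrac)


#: shipped city meta-models (coefficients as published)
AARHUS = MetaModel(c2=0.0, c1=-3.9134, c0=-0.1636, name="aarhus")
PARIS = MetaModel(c2=6.0425, c1=-8.9865, c0=-0.8939, name="paris")

SHIPPED_MODELS = {"aarhus": AARHUS, "paris": PARIS}


def pcpm(model: MetaModel, woodfrac):
    """Percentage change in PM2.5 for a woodland fraction in [0, 1].

    Accepts a scalar or array; raises for values outside [0, 1].
    """
    w = np.asarray(woodfrac, dtype=np.float64)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError(f"woodfrac outside [0, 1]: {woodfrac!r}")
    out = model.c2 * w * w + model.c1 * w + model.c0
    return float(out) if np.isscalar(woodfrac) else out


def delta_field(
    model: MetaModel,
    woodfrac: np.ndarray,
    emep_baseline: ConcentrationRaster,
) -> ConcentrationRaster:
    """Absolute PM2.5 delta per coarse cell: (pcPM(w)/100) * baseline.

    ``woodfrac`` is an array of tree fractions on the baseline's grid; the
    result is a delta-role raster, everywhere <= 0 for the shipped models.
    """
    w = np.asarray(woodfrac, dtype=np.float64)
    if w.shape != emep_baseline.grid.shape:
        raise ConfigurationError(
            f"woodfrac shape {w.shape} does not match baseline grid "
            f"{emep_baseline.grid.shape}"
        )
    delta = pcpm(model, w) / 100.0 * emep_baseline.values
    return ConcentrationRaster(emep_baseline.grid, delta, role="delta")


@dataclass
class ScenarioSurfaces:
    """Fine-resolution PM2.5 surfaces for current and scenario land cover."""

    pm25_current_fine: ConcentrationRaster
    pm25_scenario_fine: ConcentrationRaster
    delta_current_coarse: ConcentrationRaster
    delta_scenario_coarse: ConcentrationRaster


def scenario_surfaces(
    model: MetaModel,
    lc_current: LandCoverRaster,
    lc_scenario: LandCoverRaster,
    coarse_grid: GridSpec,
    emep_baseline_coarse: ConcentrationRaster,
    fine_baseline: ConcentrationRaster,
) -> ScenarioSurfaces:
    """Run the full meta-model chain for both land-cover states.

    Per coarse cell: woodland fraction (TREE class only) -> pcPM -> absolute
    delta against the coarse modelled baseline; the delta field is bilinearly
    resampled to the fine grid and added to the fine baseline.  Raises if any
    resulting fine concentration is driven to zero or below.
    """
    if lc_current.grid != lc_scenario.grid:
        raise ConfigurationError("current and scenario land cover are on different grids")
    require_aligned(coarse_grid, emep_baseline_coarse.grid)

    surfaces = {}
    deltas = {}
    for key, lc in (("current", lc_current), ("scenario", lc_scenario)):
        w = class_fraction(lc, coarse_grid, {LandClass.TREE})
        d_coarse = delta_field(model, w, emep_baseline_coarse)
        d_fine = bilinear_resample(d_coarse, fine_baseline.grid)
        pm = fine_baseline.values + d_fine.values
        if np.any(pm <= 0):
            raise ConfigurationError(
                "meta-model delta drives fine PM2.5 to <= 0; fine baseline "
                "too small for the coarse delta"
            )
        surfaces[key] = ConcentrationRaster(fine_baseline.grid, pm, role="baseline")
        deltas[key] = d_coarse
    return ScenarioSurfaces(
        pm25_current_fine=surfaces["current"],
        pm25_scenario_fine=surfaces["scenario"],
        delta_current_coarse=deltas["current"],
        delta_scenario_coarse=deltas["scenario"],
    )
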