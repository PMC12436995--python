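"""Covariate standardization shared by the generator, the regressions and the IPM.

Body size is measured in mm on [0.3, 4] and mapped linearly onto the
standardized interval [-2.5, 2.5] used as the IPM state variable.
Temperature is standardized with the mean and (population) SD of the
experimental design temperatures so that extrapolation beyond the tested
range (e.g., to 32 degC) is well defined.  Sympatric and allopatric
densities enter all models as raw counts per aquarium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: size (mm) <-> standardized z:  z = (mm - SIZE_MEAN_MM) / SIZE_SD_MM
SIZE_MEAN_MM = 2.15
SIZE_SD_MM = 0.74

SIZE_MIN_MM = 0.3
SIZE_MAX_MM = 4.0
Z_MIN = -2.5
Z_MAX = 2.5

DESIGN_TEMPERATURES_C = (14.0, 18.0, 22.0, 26.0)


def size_to_z(mm):
    """Standardize body size in mm ([0.3, 4] mm <-> [-2.5, 2.5])."""
    return (np.asarray(mm, dtype=float) - SIZE_MEAN_MM) / SIZE_SD_MM


def z_to_size(z):
    """Inverse of :func:`size_to_z`."""
    return np.asarray(z, dtype=float) * SIZE_SD_MM + SIZE_MEAN_MM


@dataclass(frozen=True)
class TemperatureScale:
    """Linear transform between degrees C and standardized temperature."""

    mean_c: float
    sd_c: float

    @classmethod
    def from_design(cls, temperatures_c=DESIGN_TEMPERATURES_C) -> "TemperatureScale":
        temps = np.asarray(temperatures_c, dtype=float)
        return cls(mean_c=float(temps.mean()), sd_c=float(temps.std()))

    def to_std(self, celsius):
        return (np.asarray(celsius, dtype=float) - self.mean_c) / self.sd_c

    def to_celsius(self, std):
        return np.asarray(std, dtype=float) * self.sd_c + self.mean_c


#: default scale: design temps 14/18/22/26 -> mean 20, SD sqrt(20)
DEFAULT_TEMPERATURE_SCALE = TemperatureScale.from_design()
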