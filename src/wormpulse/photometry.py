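"""Photometric calibration of the LED stimulation light.

The light source is characterized with a laser power meter whose sensor
integrates power over a circular aperture and is calibrated at 633 nm.
Readings taken under the ~450 nm royal-blue LED must therefore be

1. scaled by the manufacturer's wavelength correction factor, and
2. divided by the sensor area to give the average intensity (irradiance)
   seen by animals on the plate.

Defaults match the platform this package models: a 9 mm diameter sensor
and a 633 nm -> ~450 nm correction factor of 3.29.  Values are kept at
full precision internally; round only for display.
"""

from __future__ import annotations

import math

__all__ = [
    "DEFAULT_CORRECTION_FACTOR",
    "DEFAULT_SENSOR_DIAMETER_MM",
    "corrected_power",
    "intensity_from_power",
    "intensity_from_raw_power",
]

#: Manufacturer's wavelength correction from the 633 nm calibration point
#: to the LED's ~450 nm emission.
DEFAULT_CORRECTION_FACTOR = 3.29

#: Diameter of the power meter's circular sensor, in mm.
DEFAULT_SENSOR_DIAMETER_MM = 9.0


def corrected_power(
    raw_power: float, correction_factor: float = DEFAULT_CORRECTION_FACTOR
) -> float:
    """Wavelength-corrected power in mW.

    Parameters
    ----------
    raw_power : float
        Power reading in mW at the meter's calibration wavelength.
    correction_factor : float
        Dimensionless scale to the wavelength of interest.
    """
    if raw_power < 0:
        raise ValueError("raw_power must be non-negative")
    if correction_factor <= 0:
        raise ValueError("correction_factor must be positive")
    return raw_power * correction_factor


def intensity_from_power(
    power: float, sensor_diameter: float = DEFAULT_SENSOR_DIAMETER_MM
) -> float:
    """Average intensity in mW/mm^2 over a circular sensor.

    ``power`` is the (already wavelength-corrected) power in mW;
    ``sensor_diameter`` the sensor aperture in mm.  The sensor is treated
    as a flat disk, so intensity = power / (pi * (d/2)^2).
    """
    if power < 0:
        raise ValueError("power must be non-negative")
    if sensor_diameter <= 0:
        raise ValueError("sensor_diameter must be positive")
    return power / (math.pi * (sensor_diameter / 2.0) ** 2)


def intensity_from_raw_power(
    raw_power: float,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
    sensor_diameter: float = DEFAULT_SENSOR_DIAMETER_MM,
) -> float:
    """Convenience: raw meter reading -> corrected average intensity."""
    return intensity_from_power(
        corrected_power(raw_power, correction_factor), sensor_diameter
    )
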