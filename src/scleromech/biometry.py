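"""A-mode ultrasound biometry: time-of-flight conversion and globe volume.

Globe dimensions are measured along the anterior-posterior (axial),
nasal-temporal and superior-inferior directions from the time of flight of
pulse-echo A-mode ultrasound, using tissue-specific sound speeds.  Ocular
volume is estimated from the three diameters assuming an ellipsoidal globe;
with dimensions in mm the ellipsoid volume in mm^3 is numerically equal to
microlitres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SOUND_SPEED_M_S",
    "GlobeGeometry",
    "tof_to_distance",
    "ellipsoid_volume",
    "axial_resolution",
]

#: Sound speed by ocular medium, m/s.
SOUND_SPEED_M_S: dict[str, float] = {
    "cornea_sclera": 1605.0,
    "aqueous_vitreous": 1540.0,
    "lens": 1645.0,
}


@dataclass(frozen=True)
class GlobeGeometry:
    """Globe diameters (mm) and the derived ellipsoid volume (µL)."""

    axial: float
    nt: float
    si: float

    def __post_init__(self) -> None:
        for name in ("axial", "nt", "si"):
            if getattr(self, name) <= 0:
                raise ValueError(f"globe dimension {name!r} must be positive")

    @property
    def v0(self) -> float:
        """Ellipsoid volume in µL (mm^3)."""
        return ellipsoid_volume(self.axial, self.nt, self.si)


def tof_to_distance(round_trip_time: float, medium: str) -> float:
    """Convert a pulse-echo round-trip time (s) to one-way distance (mm).

    The echo travels to the interface and back, so the one-way distance is
    ``c * t / 2`` with the medium's sound speed ``c``.

    Parameters
    ----------
    round_trip_time
        Round-trip (two-way) time of flight, seconds. Must be >= 0.
    medium
        One of ``cornea_sclera``, ``aqueous_vitreous``, ``lens``.
    """
    if round_trip_time < 0:
        raise ValueError("time of flight must be non-negative")
    try:
        c = SOUND_SPEED_M_S[medium]
    except KeyError:
        raise ValueError(
            f"unknown medium {medium!r}; expected one of {sorted(SOUND_SPEED_M_S)}"
        ) from None
    return c * round_trip_time / 2.0 * 1e3  # m -> mm


def axial_resolution(sample_rate_hz: float, medium: str = "aqueous_vitreous") -> float:
    """Distance (mm) spanned by one RF sample period in pulse-echo mode.

    At 500 MHz sampling in aqueous/vitreous this is ~1.5 µm, which sets the
    resolution of time-of-flight distance measurements.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample rate must be positive")
    return tof_to_distance(1.0 / sample_rate_hz, medium)


def ellipsoid_volume(axial: float, nt: float, si: float) -> float:
    """Ellipsoid volume (µL) from three full diameters (mm).

    v = (π/6)·d1·d2·d3, symmetric in its arguments.
    """
    if axial <= 0 or nt <= 0 or si <= 0:
        raise ValueError("all globe diameters must be positive")
    return math.pi / 6.0 * axial * nt * si
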