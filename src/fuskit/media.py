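"""Acoustic media and layered propagation paths.

A :class:`Medium` bundles the three linear-acoustics material constants the
propagator needs: mass density, sound speed, and the amplitude attenuation
coefficient (Np/mm).  Presets ship for the three media of the subcutaneous
melanoma treatment geometry — coupling gel (acoustically equivalent to
water), mouse skin, and B16F10 tumor tissue — with measured values.

A :class:`LayeredPath` is an ordered stack of plane-parallel layers along
the beam axis, starting at the transducer face (z = 0, +z toward the
target).  The final layer is treated as semi-infinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "Medium",
    "Layer",
    "LayeredPath",
    "WATER",
    "ULTRASOUND_GEL",
    "MOUSE_SKIN",
    "B16F10_TUMOR",
    "MEDIA_PRESETS",
]


@dataclass(frozen=True)
class Medium:
    """Homogeneous acoustic medium.

    Parameters
    ----------
    name
        Human-readable label, also the preset key.
    density_kg_m3
        Mass density rho (kg/m^3).
    sound_speed_m_s
        Longitudinal sound speed c (m/s).
    attenuation_np_mm
        Amplitude attenuation coefficient alpha (Np/mm).
    """

    name: str
    density_kg_m3: float
    sound_speed_m_s: float
    attenuation_np_mm: float

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.sound_speed_m_s <= 0:
            raise InvalidParameterError(
                f"medium {self.name!r}: density and sound speed must be positive"
            )
        if self.attenuation_np_mm < 0:
            raise InvalidParameterError(
                f"medium {self.name!r}: attenuation must be non-negative"
            )

    @property
    def impedance_rayl(self) -> float:
        """Characteristic acoustic impedance rho*c (Pa s/m)."""
        return self.density_kg_m3 * self.sound_speed_m_s

    def wavenumber_per_mm(self, frequency_hz: float) -> complex:
        """Complex wavenumber k = 2*pi*f/c + i*alpha in rad/mm.

        The real part carries the phase velocity, the imaginary part the
        amplitude decay exp(-alpha*z).
        """
        if frequency_hz <= 0:
            raise InvalidParameterError("frequency must be positive")
        k_re = 2.0 * np.pi * frequency_hz / (self.sound_speed_m_s * 1e3)  # rad/mm
        return complex(k_re, self.attenuation_np_mm)

    def wavelength_mm(self, frequency_hz: float) -> float:
        if frequency_hz <= 0:
            raise InvalidParameterError("frequency must be positive")
        return self.sound_speed_m_s * 1e3 / frequency_hz


# Measured / literature values used for the treatment-pressure simulation.
# Gel row uses water values (acoustically near-identical to coupling gel).
ULTRASOUND_GEL = Medium("ultrasound_gel", 1000.0, 1480.0, 0.110)
WATER = Medium("water", 1000.0, 1480.0, 0.110)
MOUSE_SKIN = Medium("mouse_skin", 1060.0, 1558.0, 1.091)
B16F10_TUMOR = Medium("b16f10_tumor", 1060.0, 1521.0, 0.321)

MEDIA_PRESETS: dict[str, Medium] = {
    m.name: m for m in (ULTRASOUND_GEL, WATER, MOUSE_SKIN, B16F10_TUMOR)
}
# Common aliases used on the command line.
MEDIA_PRESETS["gel"] = ULTRASOUND_GEL
MEDIA_PRESETS["skin"] = MOUSE_SKIN
MEDIA_PRESETS["tumor"] = B16F10_TUMOR


@dataclass(frozen=True)
class Layer:
    medium: Medium
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise InvalidParameterError("layer thickness must be non-negative")


@dataclass(frozen=True)
class LayeredPath:
    """Contiguous stack of plane layers from z = 0; last layer semi-infinite.

    ``layers`` holds the finite layers in order; ``terminal`` is the medium
    filling the half-space beyond them.
    """

    layers: tuple[Layer, ...]
    terminal: Medium

    def __post_init__(self) -> None:
        for layer in self.layers:
            if layer.thickness_mm < 0:
                raise InvalidParameterError("negative layer thickness")

    @property
    def interface_depths_mm(self) -> np.ndarray:
        """Cumulative z of each interface, ending at the terminal boundary."""
        return np.cumsum([layer.thickness_mm for layer in self.layers])

    def medium_at(self, z_mm: float) -> Medium:
        depth = 0.0
        for layer in self.layers:
            depth += layer.thickness_mm
            if z_mm < depth:
                return layer.medium
        return self.terminal

    @staticmethod
    def gel_skin_tumor(
        gel_span_mm: float,
        skin_thickness_mm: float,
        gel: Medium = ULTRASOUND_GEL,
        skin: Medium = MOUSE_SKIN,
        tumor: Medium = B16F10_TUMOR,
    ) -> "LayeredPath":
        """The treatment stack: coupling gel, skin, then semi-infinite tumor.

        ``gel_span_mm`` is the transducer-to-skin standoff D (the gel-filled
        gap); the tumor starts at D + skin thickness.
        """
        return LayeredPath(
            layers=(Layer(gel, gel_span_mm), Layer(skin, skin_thickness_mm)),
            terminal=tumor,
        )
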