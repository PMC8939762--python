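"""Fresnel half-wavelength-band (FHWB) air-cavity lens design.

A planar piezoelectric plate can be turned into a self-focusing source by
masking alternate Fresnel zones with air cavities.  The zone boundaries are
chosen so that the acoustic path from each boundary to the design focus
differs by half a wavelength from its neighbour:

    sqrt(r_n^2 + F^2) = F + n * lambda / 2

which gives the closed form

    r_n = sqrt(n * lambda * F + (n * lambda / 2)^2).

Keeping the central circle and every other annulus transmitting makes all
transmitted contributions arrive within half a cycle of each other, so they
interfere constructively at the focus.

The module also covers the two resonance relations of the device: the
thickness-mode harmonic frequency of the piezoelectric plate and the
quarter-wave matching-layer thickness of the polymer coating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "LensDesign",
    "ResonatorSpec",
    "fhwb_boundary_radii",
    "transmit_annuli_from_boundaries",
    "quarter_wave_thickness",
    "harmonic_frequency",
    "design_lens",
]


def fhwb_boundary_radii(
    focal_length_mm: float, wavelength_mm: float, n_boundaries: int
) -> np.ndarray:
    """Radii of the Fresnel half-wavelength band boundaries, in mm.

    Boundary n satisfies the path-length condition
    ``sqrt(r_n**2 + F**2) == F + n*lambda/2``; radii are returned for
    n = 1..n_boundaries in ascending order.

    Parameters
    ----------
    focal_length_mm
        Design focal length F above the source plane.
    wavelength_mm
        Design wavelength lambda = c/f in the coupling medium.
    n_boundaries
        Number of boundaries to emit (>= 1).
    """
    if focal_length_mm <= 0 or wavelength_mm <= 0:
        raise InvalidParameterError("focal length and wavelength must be positive")
    if n_boundaries < 1:
        raise InvalidParameterError("n_boundaries must be >= 1")
    n = np.arange(1, n_boundaries + 1, dtype=float)
    return np.sqrt(n * wavelength_mm * focal_length_mm + (n * wavelength_mm / 2.0) ** 2)


def transmit_annuli_from_boundaries(radii_mm) -> list[tuple[float, float]]:
    """Pair boundary radii into transmitting annuli.

    The central circle (0, r1) transmits; the zone (r1, r2) is blocked by an
    air cavity; (r2, r3) transmits, and so on.  With an odd boundary count
    the outermost zone is a transmitting annulus closed by the last radius.
    Gaps between consecutive annuli are the blocked rings.
    """
    radii = np.asarray(radii_mm, dtype=float)
    if radii.ndim != 1 or radii.size < 1:
        raise InvalidParameterError("need at least one boundary radius")
    if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise InvalidParameterError("boundary radii must be positive and ascending")
    annuli = [(0.0, float(radii[0]))]
    for i in range(1, radii.size - 1, 2):
        annuli.append((float(radii[i]), float(radii[i + 1])))
    return annuli


def quarter_wave_thickness(layer_sound_speed_m_s: float, frequency_hz: float) -> float:
    """Quarter-wavelength matching-layer thickness c/(4f), in metres."""
    if layer_sound_speed_m_s <= 0 or frequency_hz <= 0:
        raise InvalidParameterError("sound speed and frequency must be positive")
    return layer_sound_speed_m_s / (4.0 * frequency_hz)


def harmonic_frequency(
    thickness_m: float, harmonic_order: int, sound_speed_m_s: float
) -> float:
    """Thickness-mode resonance f = n*c/(2*t) of a free plate, n odd."""
    if harmonic_order % 2 == 0 or harmonic_order < 1:
        raise InvalidParameterError("harmonic order must be a positive odd integer")
    if thickness_m <= 0 or sound_speed_m_s <= 0:
        raise InvalidParameterError("thickness and sound speed must be positive")
    return harmonic_order * sound_speed_m_s / (2.0 * thickness_m)


@dataclass(frozen=True)
class ResonatorSpec:
    """Thickness-mode resonator: plate thickness, odd harmonic, plate speed."""

    substrate_thickness_mm: float
    harmonic_order: int
    substrate_sound_speed_m_s: float

    def __post_init__(self) -> None:
        if self.harmonic_order % 2 == 0 or self.harmonic_order < 1:
            raise InvalidParameterError("harmonic order must be a positive odd integer")

    @property
    def operating_frequency_hz(self) -> float:
        return harmonic_frequency(
            self.substrate_thickness_mm * 1e-3,
            self.harmonic_order,
            self.substrate_sound_speed_m_s,
        )


@dataclass(frozen=True)
class LensDesign:
    """Complete FHWB lens description.

    Radii are stored in mm at full precision; the micrometre views round
    only for presentation.
    """

    focal_length_mm: float
    frequency_hz: float
    design_sound_speed_m_s: float
    boundary_radii_mm: tuple[float, ...]
    matching_layer_thickness_um: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def wavelength_mm(self) -> float:
        return self.design_sound_speed_m_s * 1e3 / self.frequency_hz

    @property
    def boundary_radii_um(self) -> np.ndarray:
        return np.asarray(self.boundary_radii_mm) * 1e3

    @property
    def transmit_annuli_mm(self) -> list[tuple[float, float]]:
        return transmit_annuli_from_boundaries(self.boundary_radii_mm)

    @property
    def transmit_annuli_um(self) -> list[tuple[float, float]]:
        return [(a * 1e3, b * 1e3) for a, b in self.transmit_annuli_mm]

    @property
    def aperture_radius_mm(self) -> float:
        """Outer radius of the outermost transmitting annulus."""
        return self.transmit_annuli_mm[-1][1]

    def path_length_residual_mm(self) -> np.ndarray:
        """|sqrt(r_n^2+F^2) - (F + n*lambda/2)| per boundary; ~0 by design."""
        r = np.asarray(self.boundary_radii_mm)
        n = np.arange(1, r.size + 1)
        return np.abs(
            np.hypot(r, self.focal_length_mm)
            - (self.focal_length_mm + n * self.wavelength_mm / 2.0)
        )

    def to_json(self) -> str:
        payload = {
            "focal_length_mm": self.focal_length_mm,
            "frequency_hz": self.frequency_hz,
            "design_sound_speed_m_s": self.design_sound_speed_m_s,
            "boundary_radii_mm": list(self.boundary_radii_mm),
            "matching_layer_thickness_um": self.matching_layer_thickness_um,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def from_json(text: str) -> "LensDesign":
        payload = json.loads(text)
        return LensDesign(
            focal_length_mm=payload["focal_length_mm"],
            frequency_hz=payload["frequency_hz"],
            design_sound_speed_m_s=payload["design_sound_speed_m_s"],
            boundary_radii_mm=tuple(payload["boundary_radii_mm"]),
            matching_layer_thickness_um=payload.get("matching_layer_thickness_um"),
            metadata=payload.get("metadata", {}),
        )


def design_lens(
    focal_length_mm: float = 5.0,
    frequency_hz: float = 20.7e6,
    design_sound_speed_m_s: float = 1465.0,
    n_boundaries: int = 11,
    matching_layer_sound_speed_m_s: float | None = None,
) -> LensDesign:
    """Design an FHWB lens; defaults give the 5 mm / 20.7 MHz treatment lens.

    ``design_sound_speed_m_s`` defaults to 1465 m/s, a room-temperature
    water value; 11 boundaries produce six transmitting regions (central
    circle + five rings).
    """
    wavelength_mm = design_sound_speed_m_s * 1e3 / frequency_hz
    radii = fhwb_boundary_radii(focal_length_mm, wavelength_mm, n_boundaries)
    matching_um = None
    if matching_layer_sound_speed_m_s is not None:
        matching_um = (
            quarter_wave_thickness(matching_layer_sound_speed_m_s, frequency_hz) * 1e6
        )
    return LensDesign(
        focal_length_mm=focal_length_mm,
        frequency_hz=frequency_hz,
        design_sound_speed_m_s=design_sound_speed_m_s,
        boundary_radii_mm=tuple(radii),
        matching_layer_thickness_um=matching_um,
    )
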