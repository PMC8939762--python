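"""Acoustic exposure indices, thermal dose, and tissue characterization.

Intensities follow the plane-wave relation I = p^2 / (2 rho c): the
spatial-peak pulse-average intensity I_SPPA uses the focal pressure
amplitude, and the temporal average I_SPTA is I_SPPA times the duty cycle
(pulse width x pulse repetition frequency).  The mechanical index is the
peak negative pressure in MPa over the square root of the frequency in
MHz.  Thermal dose uses the cumulative-equivalent-minutes metric

    CEM43 = sum_i dt_i * R^(43 - T_i),   R = 0.25 (T < 43 C), 0.5 (T >= 43 C)

with the standard piecewise rate constants.

The tissue-characterization estimators implement the substitution method:
attenuation from the through-sample insertion loss, sound speed from the
time-of-flight shift against a reference path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .media import Medium

__all__ = [
    "PulseParams",
    "DoseMetrics",
    "ThermalRecord",
    "SafetyLimits",
    "isppa",
    "ispta",
    "mechanical_index",
    "cem43",
    "cem43_const",
    "safety_report",
    "dose_metrics",
    "attenuation_from_insertion_loss",
    "sound_speed_from_tof",
    "estimate_delay",
]

# FDA track-1 diagnostic-ultrasound limits used as the default yardstick.
FDA_ISPPA_W_CM2 = 190.0
FDA_ISPTA_W_CM2 = 0.720
FDA_MI = 1.9

CEM43_R_BELOW = 0.25  # T < 43 C
CEM43_R_ABOVE = 0.5   # T >= 43 C


@dataclass(frozen=True)
class PulseParams:
    """Pulsed-drive timing: repetition frequency, pulse width, drive level."""

    prf_hz: float
    pulse_width_s: float
    drive_voltage_vpp: float | None = None

    def __post_init__(self) -> None:
        if self.prf_hz <= 0 or self.pulse_width_s <= 0:
            raise InvalidParameterError("PRF and pulse width must be positive")
        if self.duty_cycle > 1.0:
            raise InvalidParameterError(
                f"duty cycle {self.duty_cycle:.3f} exceeds 1 "
                "(pulse width longer than the repetition period)"
            )

    @property
    def duty_cycle(self) -> float:
        return self.prf_hz * self.pulse_width_s


# The treatment drive: 60 Hz PRF, 1.45 ms pulses (duty cycle 0.087), 211 Vpp.
TREATMENT_PULSE = PulseParams(prf_hz=60.0, pulse_width_s=1.45e-3,
                              drive_voltage_vpp=211.0)


@dataclass(frozen=True)
class DoseMetrics:
    i_sppa_w_cm2: float
    i_spta_w_cm2: float
    mi: float
    peak_pressure_mpa: float
    cem43_min: float | None = None


def isppa(pressure_pa: float, density_kg_m3: float, sound_speed_m_s: float) -> float:
    """Spatial-peak pulse-average intensity p^2/(2 rho c), in W/cm^2."""
    if density_kg_m3 <= 0 or sound_speed_m_s <= 0:
        raise InvalidParameterError("density and sound speed must be positive")
    if pressure_pa < 0:
        raise InvalidParameterError("pressure amplitude must be non-negative")
    i_w_m2 = pressure_pa**2 / (2.0 * density_kg_m3 * sound_speed_m_s)
    return i_w_m2 / 1e4


def isppa_in(pressure_pa: float, medium: Medium) -> float:
    """:func:`isppa` with the medium's rho and c."""
    return isppa(pressure_pa, medium.density_kg_m3, medium.sound_speed_m_s)


def ispta(i_sppa_w_cm2: float, pulse: PulseParams) -> float:
    """Temporal-average intensity: I_SPPA times the duty cycle."""
    return i_sppa_w_cm2 * pulse.duty_cycle


def mechanical_index(peak_negative_pressure_mpa: float, frequency_mhz: float) -> float:
    """MI = p_neg[MPa] / sqrt(f[MHz]); inertial-cavitation risk proxy."""
    if frequency_mhz <= 0:
        raise InvalidParameterError("frequency must be positive")
    return peak_negative_pressure_mpa / np.sqrt(frequency_mhz)


@dataclass(frozen=True)
class ThermalRecord:
    """Temperature history: times in minutes (strictly increasing), T in C."""

    t_min: np.ndarray
    temperature_c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        temp = np.asarray(self.temperature_c, dtype=float)
        if t.size == 0 or t.size != temp.size:
            raise InvalidParameterError("record needs matching, non-empty t and T")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "temperature_c", temp)

    @staticmethod
    def constant(temperature_c: float, duration_min: float) -> "ThermalRecord":
        return ThermalRecord(np.array([0.0, duration_min]),
                             np.array([temperature_c, temperature_c]))

    def concat(self, other: "ThermalRecord") -> "ThermalRecord":
        """Append ``other`` in time after this record."""
        offset = self.t_min[-1] - other.t_min[0]
        return ThermalRecord(
            np.concatenate([self.t_min, offset + other.t_min[1:]]),
            np.concatenate([self.temperature_c, other.temperature_c[1:]]),
        )


def _rate(temperature_c: np.ndarray) -> np.ndarray:
    return np.where(temperature_c < 43.0, CEM43_R_BELOW, CEM43_R_ABOVE)


def cem43(record: ThermalRecord) -> float:
    """Cumulative equivalent minutes at 43 C for a temperature history.

    Each interval contributes dt * R^(43 - T) with T the interval mean
    temperature and R the piecewise rate constant at that temperature.
    """
    dt = np.diff(record.t_min)
    t_mid = 0.5 * (record.temperature_c[:-1] + record.temperature_c[1:])
    return float(np.sum(dt * _rate(t_mid) ** (43.0 - t_mid)))


def cem43_const(temperature_c: float, duration_min: float) -> float:
    """CEM43 of a constant-temperature exposure: t * R^(43 - T)."""
    if duration_min < 0:
        raise InvalidParameterError("duration must be non-negative")
    r = CEM43_R_BELOW if temperature_c < 43.0 else CEM43_R_ABOVE
    return duration_min * r ** (43.0 - temperature_c)


@dataclass(frozen=True)
class SafetyLimits:
    i_sppa_w_cm2: float = FDA_ISPPA_W_CM2
    i_spta_w_cm2: float = FDA_ISPTA_W_CM2
    mi: float = FDA_MI


def _category(ratio: float) -> str:
    # Qualitative summary of value/limit: within a factor of two = "close".
    if ratio > 2.0:
        return "much higher"
    if ratio < 0.5:
        return "much lower"
    return "close"


def safety_report(metrics: DoseMetrics, limits: SafetyLimits = SafetyLimits()) -> dict:
    """Compare exposure metrics against diagnostic-ultrasound limits.

    A metric passes only if strictly below its limit (values equal to the
    limit fail).  Each entry reports the value, the limit, the pass flag,
    and a qualitative category ("close" within a factor of two of the
    limit, otherwise "much higher"/"much lower").
    """
    entries = {
        "i_sppa_w_cm2": (metrics.i_sppa_w_cm2, limits.i_sppa_w_cm2),
        "i_spta_w_cm2": (metrics.i_spta_w_cm2, limits.i_spta_w_cm2),
        "mi": (metrics.mi, limits.mi),
    }
    report = {}
    for name, (value, limit) in entries.items():
        report[name] = {
            "value": value,
            "limit": limit,
            "pass": bool(value < limit),
            "category": _category(value / limit) if limit > 0 else "undefined",
        }
    report["all_pass"] = all(report[n]["pass"] for n in entries)
    return report


def dose_metrics(
    pressure_pa: float,
    medium: Medium,
    pulse: PulseParams,
    frequency_hz: float,
    thermal: ThermalRecord | None = None,
) -> DoseMetrics:
    """Bundle I_SPPA, I_SPTA, MI (and CEM43 if a record is given)."""
    i_pa = isppa_in(pressure_pa, medium)
    return DoseMetrics(
        i_sppa_w_cm2=i_pa,
        i_spta_w_cm2=ispta(i_pa, pulse),
        mi=mechanical_index(pressure_pa / 1e6, frequency_hz / 1e6),
        peak_pressure_mpa=pressure_pa / 1e6,
        cem43_min=cem43(thermal) if thermal is not None else None,
    )


def attenuation_from_insertion_loss(
    amp_reference: float,
    amp_through_sample: float,
    sample_thickness_mm: float,
    alpha_reference_np_mm: float,
) -> float:
    """Sample attenuation (Np/mm) by the substitution insertion-loss method.

    A sample of known thickness replaces an equal span of reference medium
    in a through path; the amplitude ratio gives
    alpha_sample = alpha_ref + ln(A_ref / A_sample) / d.
    """
    if amp_reference <= 0 or amp_through_sample <= 0:
        raise InvalidParameterError("amplitudes must be positive")
    if sample_thickness_mm <= 0:
        raise InvalidParameterError("sample thickness must be positive")
    return alpha_reference_np_mm + float(
        np.log(amp_reference / amp_through_sample) / sample_thickness_mm
    )


def sound_speed_from_tof(
    delta_t_s: float, sample_thickness_mm: float, c_reference_m_s: float
) -> float:
    """Sample sound speed by the substitution time-of-flight method.

    ``delta_t_s`` is the arrival-time advance of the through-sample pulse
    relative to the all-reference path (positive when the sample is
    faster): 1/c_sample = 1/c_ref - dt/d.
    """
    if sample_thickness_mm <= 0:
        raise InvalidParameterError("sample thickness must be positive")
    if c_reference_m_s <= 0:
        raise InvalidParameterError("reference speed must be positive")
    d_m = sample_thickness_mm * 1e-3
    slowness = 1.0 / c_reference_m_s - delta_t_s / d_m
    if slowness <= 0:
        raise InvalidParameterError(
            "time shift implies a non-positive sound speed; check dt sign"
        )
    return 1.0 / slowness


def estimate_delay(
    reference: np.ndarray, delayed: np.ndarray, sample_rate_hz: float
) -> float:
    """Delay of ``delayed`` relative to ``reference`` by cross-correlation.

    Sub-sample resolution via a three-point parabolic fit around the
    correlation peak.  A positive return means ``delayed`` arrives later.
    """
    from scipy.signal import correlate

    a = np.asarray(reference, dtype=float)
    b = np.asarray(delayed, dtype=float)
    corr = correlate(b, a, mode="full")
    lags = np.arange(-(a.size - 1), b.size)
    idx = int(np.argmax(corr))
    if 0 < idx < corr.size - 1:
        y0, y1, y2 = corr[idx - 1], corr[idx], corr[idx + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    return float((lags[idx] + shift) / sample_rate_hz)
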