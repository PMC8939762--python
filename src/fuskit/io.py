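"""Configuration, reports, CSV interchange, and synthetic measurement fixtures.

Interface conventions
---------------------
Config and report mappings carry explicit unit suffixes on every numeric
key (``focal_length_mm``, ``frequency_hz``, ``dwell_s`` ...) so that
millimetres and micrometres can never be silently confused; validation
rejects unknown keys and keys without a recognised suffix, listing the
offenders by name.  All random generation is seeded and the seed recorded,
so two runs with one seed are byte-identical.

The synthetic generators emulate the hydrophone-characterization signals:
pulsed tone bursts (a 20.7 MHz carrier gated to an integer cycle count and
repeated at the PRF), their spectra, and linear pressure-versus-voltage
calibration data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, InvalidParameterError

__all__ = [
    "WaveformRecord",
    "BeamProfileRecord",
    "synth_pulsed_waveform",
    "waveform_spectrum",
    "spectrum_peaks",
    "pressure_voltage_fit",
    "load_config",
    "save_config",
    "validate_config",
    "save_report",
    "waveform_to_csv",
    "waveform_from_csv",
    "profile_to_csv",
    "profile_from_csv",
    "spot_table_to_csv",
    "spot_table_from_csv",
]

# Recognised unit suffixes for config keys; bare keys must be whitelisted.
_UNIT_SUFFIXES = (
    "_mm", "_um", "_m_s", "_hz", "_mhz", "_s", "_ms", "_min",
    "_mpa", "_pa", "_v", "_vpp", "_np_mm", "_kg_m3", "_w_cm2", "_c",
    "_mm_s",
)
_UNITLESS_KEYS = {
    "name", "seed", "n_boundaries", "n_planes", "n_cycles", "harmonic_order",
    "grid_convention", "z_order", "method", "medium", "media", "comment",
    "spots_per_plane", "noise_sd", "distances_mm", "width_convention",
}


@dataclass(frozen=True)
class WaveformRecord:
    """Uniformly sampled voltage or pressure trace."""

    sample_rate_hz: float
    samples: np.ndarray
    sensitivity_pa_per_v: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.size == 0 or not np.all(np.isfinite(samples)):
            raise InvalidParameterError("waveform must be non-empty and finite")
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


@dataclass(frozen=True)
class BeamProfileRecord:
    """Normalized amplitude versus position along one beam axis."""

    coordinate: np.ndarray
    amplitude: np.ndarray
    axis: str  # "axial" or "lateral"
    coordinate_unit: str = "mm"

    def __post_init__(self) -> None:
        coord = np.asarray(self.coordinate, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if coord.size != amp.size or coord.size == 0:
            raise InvalidParameterError("profile axes must match and be non-empty")
        if self.axis not in ("axial", "lateral"):
            raise InvalidParameterError("axis must be 'axial' or 'lateral'")
        peak = np.abs(amp).max()
        if peak > 0:
            amp = np.abs(amp) / peak
        object.__setattr__(self, "coordinate", coord)
        object.__setattr__(self, "amplitude", amp)


def synth_pulsed_waveform(
    frequency_hz: float,
    n_cycles: int,
    amplitude: float,
    prf_hz: float,
    noise_sd: float,
    sample_rate_hz: float,
    seed: int,
    n_bursts: int = 1,
) -> WaveformRecord:
    """Tone bursts of ``n_cycles`` at the carrier, repeated at the PRF.

    Deterministic for a fixed seed.  Refuses sample rates below 10x the
    carrier (too coarse to represent the burst).
    """
    if sample_rate_hz < 10.0 * frequency_hz:
        raise InvalidParameterError(
            f"sample rate {sample_rate_hz:g} Hz undersamples the "
            f"{frequency_hz:g} Hz carrier (need >= 10x)"
        )
    if n_cycles < 1 or n_bursts < 1:
        raise InvalidParameterError("need at least one cycle and one burst")
    burst_s = n_cycles / frequency_hz
    period_s = 1.0 / prf_hz
    if burst_s > period_s:
        raise InvalidParameterError("burst longer than the repetition period")
    n = int(round(n_bursts * period_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    phase_t = np.mod(t, period_s)
    gate = phase_t < burst_s
    signal = amplitude * np.sin(2.0 * np.pi * frequency_hz * t) * gate
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return WaveformRecord(sample_rate_hz=sample_rate_hz, samples=signal)


def waveform_spectrum(record: WaveformRecord) -> pd.DataFrame:
    """One-sided magnitude spectrum as columns (frequency_hz, magnitude).

    Magnitudes are raw rfft moduli; Parseval's identity holds as
    sum |x|^2 == (|X_0|^2 + 2 sum |X_k|^2 [+ |X_nyq|^2 for even n]) / n.
    """
    x = record.samples
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / record.sample_rate_hz)
    return pd.DataFrame({"frequency_hz": freqs, "magnitude": np.abs(spectrum)})


def spectrum_peaks(
    spectrum: pd.DataFrame, n_peaks: int = 5, min_rel_height: float = 0.05
) -> pd.DataFrame:
    """Dominant spectral peaks, strongest first."""
    from scipy.signal import find_peaks

    mag = spectrum["magnitude"].to_numpy()
    idx, _ = find_peaks(mag, height=min_rel_height * mag.max())
    if idx.size == 0:
        idx = np.array([int(np.argmax(mag))])
    order = np.argsort(mag[idx])[::-1][:n_peaks]
    return spectrum.iloc[idx[order]].reset_index(drop=True)


def pressure_voltage_fit(voltages_vpp, pressures_mpa) -> dict:
    """Least-squares line through (V_pp, MPa) calibration points.

    Returns slope (MPa/V), intercept (MPa), residuals, and a predict
    callable.  Degenerate abscissae (all voltages equal) raise.
    """
    v = np.asarray(voltages_vpp, dtype=float)
    p = np.asarray(pressures_mpa, dtype=float)
    if v.size < 2 or v.size != p.size:
        raise InvalidParameterError("need >= 2 matched (voltage, pressure) points")
    if np.ptp(v) == 0:
        raise InvalidParameterError("all voltages identical; cannot fit a line")
    design = np.column_stack([v, np.ones_like(v)])
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    residuals = p - (slope * v + intercept)
    return {
        "slope_mpa_per_v": slope,
        "intercept_mpa": intercept,
        "residuals_mpa": residuals,
        "predict": lambda volts: slope * np.asarray(volts) + intercept,
    }


def validate_config(config: dict, allowed_keys: set[str] | None = None) -> None:
    """Reject keys without a recognised unit suffix, and unknown keys.

    ``allowed_keys``, when given, is the complete schema: anything else is
    an unknown key.  Errors name every offending key.
    """
    bad_units = []
    unknown = []
    for key in config:
        if allowed_keys is not None and key not in allowed_keys:
            unknown.append(key)
            continue
        if key in _UNITLESS_KEYS:
            continue
        if not any(key.endswith(suffix) for suffix in _UNIT_SUFFIXES):
            bad_units.append(key)
    problems = []
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    if bad_units:
        problems.append(f"keys missing a unit suffix: {sorted(bad_units)}")
    if problems:
        raise ConfigError("; ".join(problems))


def require_keys(config: dict, required: set[str]) -> None:
    missing = sorted(required - set(config))
    if missing:
        raise ConfigError(f"missing required keys: {missing}")


def load_config(path, required: set[str] | None = None,
                allowed_keys: set[str] | None = None) -> dict:
    """Read a YAML or JSON config mapping and validate it."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ConfigError("config root must be a mapping")
    validate_config(config, allowed_keys)
    if required:
        require_keys(config, required)
    return config


def save_config(path, config: dict) -> None:
    validate_config(config)
    text = (
        json.dumps(config, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(config, sort_keys=True)
    )
    Path(path).write_text(text)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_report(path, payload: dict, config: dict | None = None,
                seed: int | None = None) -> dict:
    """Write a JSON report with a provenance block; returns the full document.

    Provenance records the package and numeric-library versions, the seed,
    and a hash of the driving config.  No timestamps: identical inputs
    produce identical bytes.
    """
    import scipy

    from . import __version__

    document = {
        "report": payload,
        "provenance": {
            "package": f"fuskit {__version__}",
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "seed": seed,
            "config_sha256_16": config_hash(config) if config is not None else None,
        },
    }
    Path(path).write_text(json.dumps(document, indent=2, default=_json_default))
    return document


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def profiles_from_field(fld) -> tuple[BeamProfileRecord, BeamProfileRecord]:
    """Normalized on-axis and focal-plane profiles of a simulated field.

    Returns (axial, lateral) records matching the shape of hydrophone
    beam-profile scans: normalized |p| against z on the axis, and against
    r at the plane of the on-axis maximum.
    """
    axial_amp = fld.on_axis()
    z_focus = fld.z_mm[int(np.argmax(axial_amp))]
    axial = BeamProfileRecord(fld.z_mm, axial_amp, axis="axial")
    lateral = BeamProfileRecord(
        fld.r_mm, fld.lateral_profile(z_focus), axis="lateral"
    )
    return axial, lateral


def waveform_to_csv(path, record: WaveformRecord) -> None:
    pd.DataFrame(
        {"time_s": record.times_s, "value": record.samples}
    ).to_csv(path, index=False)


def waveform_from_csv(path) -> WaveformRecord:
    df = pd.read_csv(path)
    dt = np.diff(df["time_s"].to_numpy())
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise InvalidParameterError("waveform CSV is not uniformly sampled")
    return WaveformRecord(
        sample_rate_hz=1.0 / dt[0], samples=df["value"].to_numpy()
    )


def profile_to_csv(path, profile: BeamProfileRecord) -> None:
    df = pd.DataFrame(
        {
            f"position_{profile.coordinate_unit}": profile.coordinate,
            "normalized_amplitude": profile.amplitude,
        }
    )
    df.attrs["axis"] = profile.axis
    header = f"# axis={profile.axis}\n"
    Path(path).write_text(header + df.to_csv(index=False))


def profile_from_csv(path) -> BeamProfileRecord:
    text = Path(path).read_text().splitlines()
    axis = "lateral"
    body_start = 0
    if text and text[0].startswith("# axis="):
        axis = text[0].split("=", 1)[1].strip()
        body_start = 1
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(text[body_start:])))
    pos_col = [c for c in df.columns if c.startswith("position_")][0]
    return BeamProfileRecord(
        coordinate=df[pos_col].to_numpy(),
        amplitude=df["normalized_amplitude"].to_numpy(),
        axis=axis,
        coordinate_unit=pos_col.split("_", 1)[1],
    )


def spot_table_to_csv(path, plan) -> None:
    """Flatten a ScanPlan into an (x_mm, y_mm, z_mm, order) table."""
    rows = []
    order = 0
    for z in plan.z_planes_mm():
        for x, y in plan.route:
            rows.append((x, y, z, order))
            order += 1
    pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "order"]).to_csv(
        path, index=False
    )


def spot_table_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"x_mm", "y_mm", "z_mm", "order"} - set(df.columns)
    if missing:
        raise ConfigError(f"spot table missing columns: {sorted(missing)}")
    return df.sort_values("order").reset_index(drop=True)
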