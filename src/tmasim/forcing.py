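"""Acousto-electric forcing for transcranial magneto-acoustical stimulation.

An ultrasonic pressure wave travelling through conductive tissue inside a
static magnetic field B exerts a Lorentz force on the moving ions, producing
a current density perpendicular to both the propagation axis and the field:

    J(t) = sigma * B * w * waveform(2*pi*f*t),   w = sqrt(2*Gamma/(rho*c0))

where ``sigma`` is the tissue conductivity, ``w`` the particle-speed
amplitude of the wave, ``Gamma`` the acoustic intensity, and ``f`` the
carrier frequency.  This module converts the user-facing stimulation
parameters (Gamma in W/cm^2, B in T, f in Hz) into the current density that
drives the membrane model (uA/cm^2), builds the continuous and pulsed drive
waveforms, and evaluates the diagnostic-ultrasound safety indices (mechanical
index MI, soft-tissue thermal index TI) used to judge clinical feasibility.

Unit policy: all acoustic arithmetic is carried out in SI; the two unit
conversions a user sees (W/cm^2 -> W/m^2 and A/m^2 -> uA/cm^2) each go
through a single named constant below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "TissueConstants",
    "DriveSpec",
    "SafetyInputs",
    "BRAIN_TISSUE",
    "W_PER_CM2_TO_W_PER_M2",
    "A_PER_M2_TO_UA_PER_CM2",
    "WAVEFORMS",
    "particle_speed_amplitude",
    "pressure_amplitude",
    "current_density_amplitude",
    "continuous_drive",
    "pulse_gate",
    "pulsed_drive",
    "drive_current",
    "mechanical_index",
    "thermal_index",
    "acoustic_power",
    "safety_report",
]

#: Intensity conversion, W/cm^2 -> W/m^2.
W_PER_CM2_TO_W_PER_M2 = 1.0e4

#: Current-density conversion, A/m^2 -> uA/cm^2 (1 A/m^2 = 100 uA/cm^2).
A_PER_M2_TO_UA_PER_CM2 = 100.0

#: MI normalisation constant, MPa * MHz^(1/2) (IEC 60601-2-37).
C_MI_MPA_SQRT_MHZ = 1.0

#: Soft-tissue TI normalisation constant, mW * MHz (IEC 60601-2-37).
C_TIS_MW_MHZ = 210.0

#: Carrier waveforms.  ``offset_sine`` (sin + 1, never negative) is the
#: physically effective drive; ``sine``/``cosine`` are the zero-mean forms
#: retained for the no-spiking comparison.
WAVEFORMS = ("offset_sine", "sine", "cosine")

_MODES = ("continuous", "pulsed")


@dataclass(frozen=True)
class TissueConstants:
    """Bulk acoustic/electric constants of brain tissue.

    sigma : electrical conductivity, S/m
    rho   : mass density, kg/m^3
    c0    : speed of sound, m/s
    """

    sigma: float = 0.5
    rho: float = 1120.0
    c0: float = 1540.0

    def __post_init__(self) -> None:
        for name in ("sigma", "rho", "c0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TissueConstants.{name} must be > 0")


#: Default tissue constants (grey matter).
BRAIN_TISSUE = TissueConstants()


@dataclass(frozen=True)
class DriveSpec:
    """Full description of a TMAS stimulus.

    gamma      : ultrasonic power intensity, W/cm^2
    b_field    : magnetostatic field strength, T
    freq       : ultrasound carrier frequency, Hz
    mode       : 'continuous' or 'pulsed'
    duty_cycle : on-fraction of each repetition period, (0, 1]; pulsed only
    rep_freq   : repetition frequency of the pulse gate, Hz; pulsed only
    waveform   : carrier shape; 'offset_sine' unless studying the zero-mean
                 carriers that elicit no response
    tissue     : bulk tissue constants
    """

    gamma: float
    b_field: float
    freq: float
    mode: str = "continuous"
    duty_cycle: float | None = None
    rep_freq: float | None = None
    waveform: str = "offset_sine"
    tissue: TissueConstants = field(default=BRAIN_TISSUE)

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("DriveSpec.gamma must be > 0 (W/cm^2)")
        if self.b_field < 0:
            raise ValueError("DriveSpec.b_field must be >= 0 (T)")
        if not self.freq > 0:
            raise ValueError("DriveSpec.freq must be > 0 (Hz)")
        if self.mode not in _MODES:
            raise ValueError(f"DriveSpec.mode must be one of {_MODES}")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"DriveSpec.waveform must be one of {WAVEFORMS}")
        if self.mode == "pulsed":
            if self.duty_cycle is None or not 0 < self.duty_cycle <= 1:
                raise ValueError("pulsed mode requires duty_cycle in (0, 1]")
            if self.rep_freq is None or not self.rep_freq > 0:
                raise ValueError("pulsed mode requires rep_freq > 0 (Hz)")
            if self.rep_freq > self.freq / 100.0:
                raise ValueError(
                    "rep_freq must be far below the carrier frequency "
                    f"(got RF={self.rep_freq} Hz vs f={self.freq} Hz)"
                )
        else:
            if self.duty_cycle is not None or self.rep_freq is not None:
                raise ValueError(
                    "duty_cycle/rep_freq only apply to pulsed mode"
                )


@dataclass(frozen=True)
class SafetyInputs:
    """Inputs to the acoustic safety report.

    pr3           : attenuated peak-rarefactional pressure, MPa
    freq_mhz      : acoustic working frequency, MHz
    spot_diameter : focal spot diameter, mm
    gamma         : ultrasonic power intensity, W/cm^2
    """

    pr3: float
    freq_mhz: float
    spot_diameter: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("pr3", "freq_mhz", "spot_diameter", "gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SafetyInputs.{name} must be > 0")


class CurrentDensity(NamedTuple):
    """Lorentz-force current-density amplitude in both unit systems."""

    a_per_m2: float
    ua_per_cm2: float


def particle_speed_amplitude(
    gamma: float, tissue: TissueConstants = BRAIN_TISSUE
) -> float:
    """Peak particle speed w (m/s) of a plane wave of intensity ``gamma``.

    Combines the plane-wave intensity relation Gamma = P^2 / (2 rho c0) with
    the acoustic impedance relation P = rho c0 w, giving
    w = sqrt(2 Gamma / (rho c0)) with Gamma in SI (W/m^2).
    """
    if not gamma > 0:
        raise ValueError("gamma must be > 0 (W/cm^2)")
    gamma_si = gamma * W_PER_CM2_TO_W_PER_M2
    return math.sqrt(2.0 * gamma_si / (tissue.rho * tissue.c0))


def pressure_amplitude(
    gamma: float, tissue: TissueConstants = BRAIN_TISSUE
) -> float:
    """Peak acoustic pressure P = rho c0 w, in Pa."""
    return tissue.rho * tissue.c0 * particle_speed_amplitude(gamma, tissue)


def current_density_amplitude(spec: DriveSpec) -> CurrentDensity:
    """Lorentz-force current-density amplitude J0 = sigma B w.

    Returns the amplitude in A/m^2 and in uA/cm^2 (the membrane model's
    native unit).  J0 is linear in B and scales with sqrt(Gamma).
    """
    w = particle_speed_amplitude(spec.gamma, spec.tissue)
    j_si = spec.tissue.sigma * spec.b_field * w
    return CurrentDensity(j_si, j_si * A_PER_M2_TO_UA_PER_CM2)


def _carrier(t_ms: np.ndarray, spec: DriveSpec) -> np.ndarray:
    phase = 2.0 * np.pi * spec.freq * (np.asarray(t_ms, dtype=float) * 1e-3)
    if spec.waveform == "offset_sine":
        return np.sin(phase) + 1.0
    if spec.waveform == "sine":
        return np.sin(phase)
    return np.cos(phase)


def continuous_drive(t_ms, spec: DriveSpec):
    """Continuous-wave current density J(t) in uA/cm^2, t in ms.

    For the default offset-sine carrier, J(t) = J0 (sin(2 pi f t) + 1):
    non-negative, range [0, 2 J0], time-average J0 over whole carrier
    periods.  Accepts scalars or arrays.
    """
    j0 = current_density_amplitude(spec).ua_per_cm2
    out = j0 * _carrier(t_ms, spec)
    return float(out) if np.isscalar(t_ms) else out


def pulse_gate(t_s, rep_freq: float, duty_cycle: float):
    """Square-wave gate: 1 during the first ``duty_cycle`` fraction of each
    repetition period 1/RF, else 0.

    The on-window of period n is the half-open interval
    ((n-1)/RF, (n-1+DC)/RF]; in particular the gate is 0 at t = 0 and a
    duty cycle of exactly 1 gives gate == 1 for all t > 0.  t in seconds.
    """
    if not rep_freq > 0:
        raise ValueError("rep_freq must be > 0 (Hz)")
    if not 0 < duty_cycle <= 1:
        raise ValueError("duty_cycle must be in (0, 1]")
    t_arr = np.asarray(t_s, dtype=float)
    u = t_arr * rep_freq
    frac = u - np.floor(u)
    # A point exactly on a period boundary belongs to the *previous* period
    # (right-closed convention), so treat frac == 0 as frac == 1.
    frac = np.where(frac == 0.0, 1.0, frac)
    gate = np.where((t_arr > 0) & (frac <= duty_cycle), 1.0, 0.0)
    return float(gate) if np.isscalar(t_s) else gate


def pulsed_drive(t_ms, spec: DriveSpec):
    """Pulsed current density: the square-wave gate applied multiplicatively
    to the full continuous carrier (offset included).  t in ms."""
    if spec.mode != "pulsed":
        raise ValueError("pulsed_drive requires a DriveSpec with mode='pulsed'")
    t_arr = np.asarray(t_ms, dtype=float)
    gate = pulse_gate(t_arr * 1e-3, spec.rep_freq, spec.duty_cycle)
    out = gate * (current_density_amplitude(spec).ua_per_cm2 * _carrier(t_arr, spec))
    return float(out) if np.isscalar(t_ms) else out


def drive_current(t_ms, spec: DriveSpec):
    """J(t) in uA/cm^2 for either mode (dispatch on ``spec.mode``)."""
    if spec.mode == "pulsed":
        return pulsed_drive(t_ms, spec)
    return continuous_drive(t_ms, spec)


def mechanical_index(pr3: float, freq_mhz: float) -> float:
    """Mechanical index MI = p_r.3 / (sqrt(f) * C_MI), dimensionless.

    ``pr3`` is the attenuated peak-rarefactional pressure in MPa, ``freq_mhz``
    the working frequency in MHz; C_MI = 1 MPa MHz^(1/2).
    """
    if not pr3 > 0 or not freq_mhz > 0:
        raise ValueError("mechanical_index inputs must be > 0")
    return pr3 / (math.sqrt(freq_mhz) * C_MI_MPA_SQRT_MHZ)


def thermal_index(power_mw: float, freq_mhz: float) -> float:
    """Soft-tissue thermal index TI = W f / C_TIS for unscanned modes.

    ``power_mw`` is the acoustic output power in mW; C_TIS = 210 mW MHz.
    """
    if not power_mw > 0 or not freq_mhz > 0:
        raise ValueError("thermal_index inputs must be > 0")
    return power_mw * freq_mhz / C_TIS_MW_MHZ


def acoustic_power(gamma: float, spot_diameter_mm: float) -> tuple[float, float]:
    """(focal spot area in cm^2, acoustic power in mW) of a circular spot.

    area = pi (d/2)^2, power = Gamma * area, with Gamma in W/cm^2.
    """
    if not gamma > 0 or not spot_diameter_mm > 0:
        raise ValueError("acoustic_power inputs must be > 0")
    radius_cm = spot_diameter_mm / 10.0 / 2.0
    area_cm2 = math.pi * radius_cm**2
    power_mw = gamma * area_cm2 * 1000.0
    return area_cm2, power_mw


def safety_report(inputs: SafetyInputs) -> dict[str, float]:
    """MI, TI, focal-spot area and acoustic power for a stimulus.

    TI is evaluated at the power implied by the intensity and spot size.
    Both indices should stay below 1 for the regime considered safe in
    diagnostic ultrasound.
    """
    area_cm2, power_mw = acoustic_power(inputs.gamma, inputs.spot_diameter)
    return {
        "mi": mechanical_index(inputs.pr3, inputs.freq_mhz),
        "ti": thermal_index(power_mw, inputs.freq_mhz),
        "spot_area_cm2": area_cm2,
        "power_mw": power_mw,
    }
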