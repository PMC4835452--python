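"""Declarative parameter sweeps over the TMAS stimulation space.

Six presets (``fig4`` .. ``fig9``) sweep one stimulation parameter each
while holding the others at the standard operating point (B = 3 T,
Gamma = 3 W/cm^2, f = 500 kHz; pulsed runs add DC = 50 %, RF = 10 Hz):

    fig4  magnetostatic field B, 0.5-7 T          (continuous)
    fig5  ultrasonic power Gamma, 1-100 W/cm^2    (continuous)
    fig6  carrier frequency f, 200-700 kHz        (continuous)
    fig7  ultrasonic power Gamma, 1-100 W/cm^2    (pulsed)
    fig8  duty cycle DC, 5-95 %                   (pulsed)
    fig9  repetition frequency RF, 1-100 Hz       (pulsed)

Each sweep point runs a full simulation and reduces it to one summary row
(AMP/ISI/FR/spike count).  "Smoke" grids restrict each sweep to the few
showcase values of the corresponding experiment; full grids cover the whole
stated range.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .forcing import DriveSpec, WAVEFORMS
from .hh_core import HHParams, HHState, ionic_currents
from .integrator import DEFAULT_DT_MS, SimConfig, SimulationResult, simulate
from .metrics import detect_spikes, summarize

__all__ = [
    "SweepSpec",
    "PRESETS",
    "preset_sweep",
    "default_duration",
    "run_sweep",
    "run_figure2_comparison",
    "load_config",
    "ConfigError",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

SWEEPABLE = ("b_field", "gamma", "freq", "duty_cycle", "rep_freq")

SUMMARY_COLUMNS = [
    "b_field_T",
    "gamma_W_cm2",
    "freq_Hz",
    "mode",
    "duty_cycle",
    "rep_freq_Hz",
    "amp_mV",
    "isi_ms",
    "fr_per_cycle",
    "n_spikes",
]

#: Parameter ranges of the study; values outside trigger an error unless
#: ``allow_extrapolation`` is set on the sweep.
PARAM_RANGES = {
    "b_field": (0.5, 7.0),
    "gamma": (1.0, 100.0),
    "freq": (200e3, 700e3),
    "duty_cycle": (0.05, 0.95),
    "rep_freq": (1.0, 100.0),
}

#: Standard operating point shared by all presets.
_BASE_CONTINUOUS = dict(gamma=3.0, b_field=3.0, freq=500e3, mode="continuous")
_BASE_PULSED = dict(
    gamma=3.0, b_field=3.0, freq=500e3, mode="pulsed", duty_cycle=0.5,
    rep_freq=10.0,
)

# (swept parameter, base drive kwargs, full grid, smoke grid)
_PRESET_TABLE = {
    "fig4": ("b_field", _BASE_CONTINUOUS,
             tuple(np.arange(0.5, 7.01, 0.5)), (0.5, 1.0, 4.0, 7.0)),
    "fig5": ("gamma", _BASE_CONTINUOUS,
             (1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
             (1.0, 10.0, 60.0, 100.0)),
    "fig6": ("freq", _BASE_CONTINUOUS,
             (200e3, 300e3, 400e3, 500e3, 600e3, 700e3),
             (200e3, 500e3, 700e3)),
    "fig7": ("gamma", _BASE_PULSED,
             (1.0, 10.0, 30.0, 60.0, 100.0), (1.0, 10.0, 30.0, 60.0, 100.0)),
    "fig8": ("duty_cycle", _BASE_PULSED,
             tuple(np.round(np.arange(0.05, 0.951, 0.05), 2)),
             (0.05, 0.5, 0.95)),
    "fig9": ("rep_freq", _BASE_PULSED,
             (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0), (5.0, 20.0, 100.0)),
}

PRESETS = tuple(_PRESET_TABLE)


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sweep over a stimulation parameter.

    parameter : which DriveSpec field is swept (one of ``SWEEPABLE``)
    values    : grid of values, reported in ascending order
    base      : DriveSpec supplying every non-swept parameter
    sim       : integration settings; None derives the duration per point
                (500 ms continuous; pulsed at least 3 repetition periods)
    """

    parameter: str
    values: tuple[float, ...]
    base: DriveSpec
    sim: SimConfig | None = None
    label: str = ""
    allow_extrapolation: bool = False

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(
                f"swept parameter must be one of {SWEEPABLE}, "
                f"got {self.parameter!r}"
            )
        if len(self.values) == 0:
            raise ValueError("sweep needs at least one value")
        if not self.allow_extrapolation:
            lo, hi = PARAM_RANGES[self.parameter]
            bad = [v for v in self.values if not lo <= v <= hi]
            if bad:
                raise ValueError(
                    f"values {bad} for {self.parameter!r} fall outside the "
                    f"studied range [{lo:g}, {hi:g}]; pass "
                    "allow_extrapolation=True to override"
                )


def preset_sweep(name: str, smoke: bool = True) -> SweepSpec:
    """Build the sweep for one of the named experiments (``fig4``..``fig9``).

    ``smoke=True`` (default) restricts the grid to the experiment's showcase
    values; ``smoke=False`` covers the full stated range.
    """
    if name not in _PRESET_TABLE:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESETS}")
    parameter, base_kwargs, full, smoke_grid = _PRESET_TABLE[name]
    values = tuple(float(v) for v in (smoke_grid if smoke else full))
    base = DriveSpec(**base_kwargs)
    return SweepSpec(parameter=parameter, values=values, base=base, label=name)


def default_duration(drive: DriveSpec) -> float:
    """Simulated duration (ms) for one sweep point: 500 ms for continuous
    stimulation; for pulsed, at least 3 repetition periods so slow gates
    (RF = 1 Hz) still see multiple bursts."""
    if drive.mode == "pulsed":
        return max(500.0, 3e3 / drive.rep_freq)
    return 500.0


def _point_drive(spec: SweepSpec, value: float) -> DriveSpec:
    return replace(spec.base, **{spec.parameter: float(value)})


def summary_row(drive: DriveSpec, result: SimulationResult) -> dict:
    s = summarize(result, drive)
    return {
        "b_field_T": drive.b_field,
        "gamma_W_cm2": drive.gamma,
        "freq_Hz": drive.freq,
        "mode": drive.mode,
        "duty_cycle": drive.duty_cycle if drive.mode == "pulsed" else math.nan,
        "rep_freq_Hz": drive.rep_freq if drive.mode == "pulsed" else math.nan,
        "amp_mV": s.amp_mean,
        "isi_ms": s.isi_mean,
        "fr_per_cycle": s.fr_per_cycle if s.fr_per_cycle is not None else math.nan,
        "n_spikes": s.n_spikes,
    }


def run_sweep(spec: SweepSpec, params: HHParams = HHParams()) -> pd.DataFrame:
    """Run every point of a sweep and return one summary row per value,
    ordered by the swept value.  Deterministic; a failing point aborts the
    sweep with the offending value named."""
    rows = []
    for value in sorted(spec.values):
        drive = _point_drive(spec, value)
        cfg = spec.sim or SimConfig(duration=default_duration(drive))
        t0 = time.perf_counter()
        try:
            result = simulate(params, drive, cfg)
            row = summary_row(drive, result)
        except Exception as exc:
            raise RuntimeError(
                f"sweep {spec.label or spec.parameter} failed at "
                f"{spec.parameter}={value:g}: {exc}"
            ) from exc
        rows.append(row)
        logger.info(
            "sweep %s: %s=%g -> %d spikes (%.1f s)",
            spec.label or spec.parameter, spec.parameter, value,
            row["n_spikes"], time.perf_counter() - t0,
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def run_figure2_comparison(
    gamma: float = 3.0,
    b_field: float = 3.0,
    freq: float = 500e3,
    duration: float = 200.0,
    params: HHParams = HHParams(),
) -> pd.DataFrame:
    """Zero-mean sine carrier vs. offset-sine carrier at equal intensity.

    A pure sine drive averages to zero over each microsecond-scale acoustic
    period, so the membrane, which low-pass filters the carrier, never
    depolarises and no sodium current develops.  The offset sine has the
    same amplitude but a positive mean and does elicit spikes at
    suprathreshold intensity.  Returns one row per carrier with the spike
    count and the peak sodium-current magnitude.
    """
    rows = []
    for waveform in ("sine", "offset_sine"):
        drive = DriveSpec(
            gamma=gamma, b_field=b_field, freq=freq, waveform=waveform
        )
        res = simulate(params, drive, SimConfig(duration=duration))
        train = detect_spikes(res)
        i_na, _, _ = ionic_currents(
            HHState(res.v, res.m, res.h, res.n), params
        )
        rows.append(
            {
                "waveform": waveform,
                "n_spikes": len(train),
                "peak_na_current_uA_cm2": float(np.max(np.abs(i_na))),
            }
        )
    return pd.DataFrame(rows)


class ConfigError(ValueError):
    """A run configuration file failed validation."""


_DRIVE_KEYS = {
    "gamma", "b_field", "freq", "mode", "duty_cycle", "rep_freq", "waveform"
}
_SIM_KEYS = {"duration", "dt", "record_stride"}
_SWEEP_KEYS = {"parameter", "values", "allow_extrapolation"}
_TOP_KEYS = {"preset", "smoke", "sweep", "drive", "sim"}


def _check_keys(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under '{path}'; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path):
    """Load a YAML run configuration.

    Returns a :class:`SweepSpec` when the file names a ``preset`` or a
    ``sweep`` section, otherwise a ``(DriveSpec, SimConfig)`` pair for a
    single simulation.  Unknown keys and invalid values are rejected with
    the offending key path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<top>")

    sim_cfg = None
    if "sim" in raw:
        _check_keys(raw["sim"], _SIM_KEYS, "sim")
        try:
            sim_cfg = SimConfig(**{k: v for k, v in raw["sim"].items()})
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"sim: {exc}") from exc

    if "preset" in raw:
        spec = preset_sweep(raw["preset"], smoke=bool(raw.get("smoke", True)))
        if sim_cfg is not None:
            spec = dataclasses.replace(spec, sim=sim_cfg)
        return spec

    drive = None
    if "drive" in raw:
        _check_keys(raw["drive"], _DRIVE_KEYS, "drive")
        try:
            drive = DriveSpec(**{k: float(v) if k not in ("mode", "waveform")
                                 else v for k, v in raw["drive"].items()})
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"drive: {exc}") from exc

    if "sweep" in raw:
        if drive is None:
            raise ConfigError("a 'sweep' section requires a 'drive' section")
        _check_keys(raw["sweep"], _SWEEP_KEYS, "sweep")
        try:
            return SweepSpec(
                parameter=raw["sweep"]["parameter"],
                values=tuple(float(v) for v in raw["sweep"]["values"]),
                base=drive,
                sim=sim_cfg,
                allow_extrapolation=bool(
                    raw["sweep"].get("allow_extrapolation", False)
                ),
            )
        except KeyError as exc:
            raise ConfigError(f"sweep: missing key {exc}") from exc
        except ValueError as exc:
            raise ConfigError(f"sweep: {exc}") from exc

    if drive is None:
        raise ConfigError(
            "config must contain 'preset', 'sweep'+'drive', or 'drive'"
        )
    if sim_cfg is None:
        sim_cfg = SimConfig(duration=default_duration(drive))
    return drive, sim_cfg
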