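"""Deterministic fixed-step integration of the driven membrane model.

Fixed-step classical Runge-Kutta (RK4) rather than an adaptive solver: the
sub-millisecond ultrasound carrier imposes a hard resolution floor anyway
(>= 20 steps per acoustic period), and a fixed step makes every run
bit-reproducible.  Also hosts the bisection search for the constant-current
firing threshold (the subcritical Hopf point of the resting state, near
9.78 uA/cm^2 for the standard parameter set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .forcing import DriveSpec, current_density_amplitude
from .hh_core import HHParams, HHState, INITIAL_STATE

__all__ = [
    "SimConfig",
    "SimulationResult",
    "simulate",
    "find_firing_threshold",
    "DEFAULT_DT_MS",
    "MIN_STEPS_PER_PERIOD",
]

#: Default step, ms: 40 steps per period of a 500 kHz carrier.
DEFAULT_DT_MS = 5e-5

#: Oscillatory drives must be resolved by at least this many steps/period.
MIN_STEPS_PER_PERIOD = 20

#: Cap on recorded samples; the stride is enlarged to stay below it.
MAX_RECORDED_SAMPLES = 1_000_000

_WAVEFORM_CODES = {
    "offset_sine": _kernels.DRIVE_OFFSET_SINE,
    "sine": _kernels.DRIVE_SINE,
    "cosine": _kernels.DRIVE_COSINE,
}


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    duration      : total simulated time, ms
    dt            : integration step, ms
    record_stride : steps between recorded samples; None picks the smallest
                    stride keeping at most ~10^6 recorded samples
    initial_state : membrane state at t = 0
    """

    duration: float
    dt: float = DEFAULT_DT_MS
    record_stride: int | None = None
    initial_state: HHState = field(default_factory=lambda: INITIAL_STATE)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("SimConfig.dt must be > 0")
        if not self.duration >= 10 * self.dt:
            raise ValueError("SimConfig.duration must be >= 10*dt")
        if self.record_stride is not None and self.record_stride < 1:
            raise ValueError("SimConfig.record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def resolved_stride(self) -> int:
        if self.record_stride is not None:
            return self.record_stride
        return max(1, -(-(self.n_steps + 1) // MAX_RECORDED_SAMPLES))


@dataclass
class SimulationResult:
    """Recorded trajectory of one run.

    Arrays share a uniform, strictly increasing time grid (ms); ``i_ext`` is
    the applied current density (uA/cm^2) evaluated at the recorded times.
    ``config`` and ``drive`` echo the inputs for provenance.
    """

    t: np.ndarray
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    i_ext: np.ndarray
    config: SimConfig
    drive: DriveSpec | float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t,
                "v_mV": self.v,
                "m": self.m,
                "h": self.h,
                "n": self.n,
                "i_ext_uA_cm2": self.i_ext,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _drive_params(drive) -> tuple[int, bool, float, float, float, float]:
    """Map a drive description onto the kernel's (code, gated, J0, f, RF, DC)."""
    if isinstance(drive, (int, float)):
        if not np.isfinite(drive):
            raise ValueError("constant drive must be finite")
        return _kernels.DRIVE_CONSTANT, False, float(drive), 0.0, 0.0, 1.0
    if isinstance(drive, DriveSpec):
        j0 = current_density_amplitude(drive).ua_per_cm2
        code = _WAVEFORM_CODES[drive.waveform]
        if drive.mode == "pulsed":
            return code, True, j0, drive.freq, drive.rep_freq, drive.duty_cycle
        return code, False, j0, drive.freq, 0.0, 1.0
    raise TypeError(
        "drive must be a DriveSpec or a constant current density in uA/cm^2"
    )


def simulate(
    params: HHParams,
    drive: DriveSpec | float,
    config: SimConfig,
) -> SimulationResult:
    """Integrate the driven membrane; deterministic (bit-identical reruns).

    ``drive`` is either a :class:`~tmasim.forcing.DriveSpec` (the TMAS
    stimulus) or a plain number, interpreted as a constant current density
    in uA/cm^2.  The drive is evaluated analytically at the RK4 sub-step
    times, so the carrier is never sample-and-hold aliased.

    Raises ValueError when ``dt`` under-resolves an oscillatory carrier and
    RuntimeError (naming the step index) if the state turns non-finite.
    """
    code, gated, j0, freq_hz, rep_freq, duty = _drive_params(drive)
    if code != _kernels.DRIVE_CONSTANT:
        period_ms = 1e3 / freq_hz
        max_dt = period_ms / MIN_STEPS_PER_PERIOD
        if config.dt > max_dt:
            raise ValueError(
                f"dt={config.dt:g} ms under-resolves the {freq_hz:g} Hz carrier; "
                f"use dt <= {max_dt:g} ms ({MIN_STEPS_PER_PERIOD} steps/period)"
            )

    s0 = config.initial_state
    out = _kernels.rk4_integrate(
        float(s0.v), float(s0.m), float(s0.h), float(s0.n),
        float(config.dt), config.n_steps, config.resolved_stride(),
        code, gated, j0, freq_hz, rep_freq, duty,
        params.cm, params.g_na, params.g_k, params.g_l,
        params.v_na, params.v_k, params.v_l, params.phi,
    )
    t, v, m, h, n, i_ext, bad_step = out
    if bad_step != -1:
        raise RuntimeError(
            f"state became non-finite at step {bad_step} "
            f"(t = {bad_step * config.dt:g} ms); reduce dt"
        )
    return SimulationResult(t, v, m, h, n, i_ext, config, drive)


def _sustains_firing(
    i_const: float,
    params: HHParams,
    duration: float,
    dt: float,
    window: tuple[float, float],
    min_spikes: int,
    probe_mv: float,
) -> bool:
    from .hh_core import resting_equilibrium
    from .metrics import detect_spikes  # local import avoids a module cycle

    eq = resting_equilibrium(float(i_const), params)
    start = HHState(v=eq.v + probe_mv, m=eq.m, h=eq.h, n=eq.n)
    res = simulate(
        params, float(i_const),
        SimConfig(duration=duration, dt=dt, initial_state=start),
    )
    train = detect_spikes(res)
    lo, hi = window
    return int(np.count_nonzero((train.times >= lo) & (train.times <= hi))) >= min_spikes


def find_firing_threshold(
    params: HHParams = HHParams(),
    i_low: float = 5.0,
    i_high: float = 15.0,
    tol: float = 0.01,
    *,
    duration: float = 500.0,
    dt: float = 1e-3,
    window: tuple[float, float] = (200.0, 500.0),
    min_spikes: int = 10,
    probe_mv: float = 1.0,
) -> float:
    """Constant-current firing threshold, by bisection, in uA/cm^2.

    The threshold located is the current at which the *resting equilibrium
    itself* turns unstable (the subcritical Hopf point, near 9.78 uA/cm^2
    for the default parameter set), above which the model fires
    periodically no matter how gently the current is reached.  Each level is
    classified by simulation: the run starts at the equilibrium state for
    that current, displaced by a small probe (``probe_mv``, default 1 mV --
    about 1 % of a spike height), and the level "sustains firing" when at
    least ``min_spikes`` spikes fall inside ``window`` (ms) of a
    ``duration`` ms run.  Probing stability this way, rather than stepping
    the current onto the resting cell, avoids latching the bistable
    limit cycle that coexists with the stable rest state a few uA/cm^2
    below the Hopf point (down to the saddle-node of periodic orbits near
    6.3 uA/cm^2) -- a step onset lands in the cycle's basin and would
    report that lower onset current instead.

    ``i_low`` must not sustain firing and ``i_high`` must; the bracket
    midpoint is returned once the bracket is narrower than ``tol``.  The
    pipeline is deterministic, so repeated calls return bit-identical
    values.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if not i_low < i_high:
        raise ValueError("require i_low < i_high")

    def fires(i):
        return _sustains_firing(
            i, params, duration, dt, window, min_spikes, probe_mv
        )

    if fires(i_low):
        raise ValueError(
            f"invalid bracket: i_low={i_low:g} uA/cm^2 already sustains firing"
        )
    if not fires(i_high):
        raise ValueError(
            f"invalid bracket: i_high={i_high:g} uA/cm^2 does not sustain firing"
        )
    lo, hi = float(i_low), float(i_high)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
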