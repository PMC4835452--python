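"""Hodgkin-Huxley membrane model in the shifted voltage frame.

The classical four-variable conductance-based model

    Cm dV/dt = I_ext - [ gNa m^3 h (V - VNa) + gK n^4 (V - VK) + gL (V - VL) ]
    dx/dt    = phi [ alpha_x(V) (1 - x) - beta_x(V) x ],   x in {m, h, n}

written in the frame where the resting potential is ~0 mV (the historical
squid-axon convention, i.e. absolute potentials shifted by +65 mV) and
depolarisation is positive.  All constants below assume this frame;
converting to the modern frame would falsify every rate function.

phi = 3^((T - 6.3)/10) is the Q10 temperature factor applied to the gating
kinetics; at the reference temperature 6.3 degC phi = 1.

Voltages are mV, time is ms, currents are uA/cm^2, conductances mS/cm^2,
capacitance uF/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "HHParams",
    "HHState",
    "INITIAL_STATE",
    "RateConstants",
    "rate_constants",
    "steady_state_gating",
    "temperature_factor",
    "ionic_currents",
    "derivatives",
    "SINGULARITY_GUARD",
]

#: Half-width (mV) of the band around the removable singularities of
#: alpha_m (V=25) and alpha_n (V=10) inside which the analytic limit value
#: is substituted.  Near 0/0 the direct formula suffers catastrophic
#: cancellation; the limits (1.0 and 0.1 respectively) are exact.
SINGULARITY_GUARD = 1e-7


@dataclass(frozen=True)
class HHParams:
    """Fixed membrane parameters (squid giant axon, shifted frame)."""

    cm: float = 1.0          # membrane capacitance, uF/cm^2
    g_na: float = 120.0      # maximal Na+ conductance, mS/cm^2
    g_k: float = 36.0        # maximal K+ conductance, mS/cm^2
    g_l: float = 0.3         # leak conductance, mS/cm^2
    v_na: float = 115.0      # Na+ reversal potential, mV
    v_k: float = -12.0       # K+ reversal potential, mV
    v_l: float = 10.59       # leak reversal potential, mV
    temperature: float = 6.3  # degC

    def __post_init__(self) -> None:
        if not self.cm > 0:
            raise ValueError("HHParams.cm must be > 0")
        for name in ("g_na", "g_k", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"HHParams.{name} must be >= 0")

    @property
    def phi(self) -> float:
        """Temperature factor applied to gating kinetics."""
        return temperature_factor(self.temperature)


@dataclass
class HHState:
    """Instantaneous membrane state: potential (mV) and gating variables.

    Fields may be scalars or equally-shaped arrays (trajectories).
    """

    v: float | np.ndarray
    m: float | np.ndarray
    h: float | np.ndarray
    n: float | np.ndarray

    def __post_init__(self) -> None:
        for name in ("m", "h", "n"):
            x = np.asarray(getattr(self, name))
            if np.any(x < 0) or np.any(x > 1):
                raise ValueError(f"HHState.{name} must lie in [0, 1]")


#: Initial condition used throughout: resting potential with the gating
#: variables at (m, h, n) = (0.053, 0.596, 0.317), their steady-state values
#: at V = 0 rounded to three decimals.
INITIAL_STATE = HHState(v=0.0, m=0.053, h=0.596, n=0.317)


class RateConstants(NamedTuple):
    alpha_m: float | np.ndarray
    beta_m: float | np.ndarray
    alpha_h: float | np.ndarray
    beta_h: float | np.ndarray
    alpha_n: float | np.ndarray
    beta_n: float | np.ndarray


def rate_constants(v) -> RateConstants:
    """Voltage-dependent channel opening/closing rates, 1/ms.

    alpha_m(V) = 0.1 (25 - V) / [exp((25 - V)/10) - 1]
    beta_m(V)  = 4 exp(-V/18)
    alpha_h(V) = 0.07 exp(-V/20)
    beta_h(V)  = 1 / [exp((30 - V)/10) + 1]
    alpha_n(V) = 0.01 (10 - V) / [exp((10 - V)/10) - 1]
    beta_n(V)  = 0.125 exp(-V/80)

    The 0/0 points of alpha_m (V=25) and alpha_n (V=10) are replaced by
    their analytic limits 1.0 and 0.1 within ``SINGULARITY_GUARD``.
    Accepts scalars or arrays.
    """
    scalar = np.isscalar(v)
    va = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(va)):
        raise ValueError("membrane potential must be finite")

    x = 25.0 - va
    near_m = np.abs(x) < SINGULARITY_GUARD
    xs = np.where(near_m, 1.0, x)  # dummy value inside the guard band
    alpha_m = np.where(near_m, 1.0, 0.1 * xs / np.expm1(xs / 10.0))
    beta_m = 4.0 * np.exp(-va / 18.0)

    alpha_h = 0.07 * np.exp(-va / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - va) / 10.0) + 1.0)

    y = 10.0 - va
    near_n = np.abs(y) < SINGULARITY_GUARD
    ys = np.where(near_n, 1.0, y)
    alpha_n = np.where(near_n, 0.1, 0.01 * ys / np.expm1(ys / 10.0))
    beta_n = 0.125 * np.exp(-va / 80.0)

    rates = (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)
    if scalar:
        return RateConstants(*(float(r) for r in rates))
    return RateConstants(*rates)


def steady_state_gating(v):
    """Steady-state gate values (m_inf, h_inf, n_inf) = alpha/(alpha+beta).

    At V = 0 these are ~(0.053, 0.596, 0.318) -- the model's resting state.
    """
    r = rate_constants(v)
    m_inf = r.alpha_m / (r.alpha_m + r.beta_m)
    h_inf = r.alpha_h / (r.alpha_h + r.beta_h)
    n_inf = r.alpha_n / (r.alpha_n + r.beta_n)
    return m_inf, h_inf, n_inf


def temperature_factor(temperature: float) -> float:
    """Q10 factor phi = 3^((T - 6.3)/10) scaling the gating kinetics."""
    if not np.isfinite(temperature):
        raise ValueError("temperature must be finite")
    return float(3.0 ** ((temperature - 6.3) / 10.0))


def ionic_currents(state: HHState, params: HHParams = HHParams()):
    """Ionic currents (i_na, i_k, i_l) in uA/cm^2, outward positive.

    i_na = gNa m^3 h (V - VNa);  i_k = gK n^4 (V - VK);  i_l = gL (V - VL).
    Sodium current is negative (inward) for 0 < V < VNa.
    """
    v, m, h, n = state.v, state.m, state.h, state.n
    i_na = params.g_na * m**3 * h * (v - params.v_na)
    i_k = params.g_k * n**4 * (v - params.v_k)
    i_l = params.g_l * (v - params.v_l)
    return i_na, i_k, i_l


def resting_equilibrium(i_ext: float, params: HHParams = HHParams()) -> HHState:
    """Equilibrium state of the membrane under a constant current (uA/cm^2).

    Solves for the potential V* at which the steady-state ionic currents
    balance ``i_ext`` (with every gate at its steady-state value), i.e. the
    fixed point whose stability the firing threshold probes.  Unique for
    physiological current levels.
    """
    from scipy.optimize import brentq

    def residual(v):
        m, h, n = steady_state_gating(v)
        i_na, i_k, i_l = ionic_currents(HHState(v, m, h, n), params)
        return i_ext - (i_na + i_k + i_l)

    v_eq = brentq(residual, -50.0, 60.0, xtol=1e-12)
    m, h, n = steady_state_gating(v_eq)
    return HHState(v=float(v_eq), m=float(m), h=float(h), n=float(n))


def derivatives(state: HHState, i_ext, params: HHParams = HHParams()):
    """Time derivatives (dv, dm, dh, dn) of the driven membrane.

    ``i_ext`` is the applied current density in uA/cm^2; it enters dV/dt
    additively with coefficient 1/Cm.  Gating derivatives vanish exactly
    when a gate sits at its steady-state value.
    """
    if not np.all(np.isfinite(np.asarray(i_ext, dtype=float))):
        raise ValueError("i_ext must be finite")
    i_na, i_k, i_l = ionic_currents(state, params)
    r = rate_constants(state.v)
    phi = params.phi
    dv = (i_ext - (i_na + i_k + i_l)) / params.cm
    dm = phi * (r.alpha_m * (1.0 - state.m) - r.beta_m * state.m)
    dh = phi * (r.alpha_h * (1.0 - state.h) - r.beta_h * state.h)
    dn = phi * (r.alpha_n * (1.0 - state.n) - r.beta_n * state.n)
    return dv, dm, dh, dn
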