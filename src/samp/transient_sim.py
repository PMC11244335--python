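"""Time-domain lumped-network simulation of repeated strain cycles.

The actuator is a compliant chamber (compliance ``C``, uL/Pa) whose
unstressed capacity dilates with strain, ``V_act(eps) = V0 (1 + beta*eps)``;
its gauge pressure drives flow through the two pumping branches to
atmospheric outlets.  With ``P`` the gauge pressure and ``Q_i = P / R_i``
the flow from the actuator into branch ``i``, the state equation is

    C dP/dt = -V0 * beta * deps/dt - P * (1/R_L + 1/R_R)

Each branch resistance is the strain-dependent pumping-channel resistance
plus, for the non-continuous design, the observation channel's per-length
resistance times its liquid-filled length (tracked by the meniscus state).
Capillary pressure and the air column beyond the menisci are neglected.

The strain waveform is a piecewise-linear trapezoid; the integrator walks
the linear segments with a fixed-step classical RK4 (step <= tau/100 by
default), so runs are deterministic.  Zero-duration ramps are treated as
ideal steps: an instantaneous pressure jump ``dP = -V0*beta*deps/C``,
mirroring the quasi-static theory's instantaneous-load assumption.  The
relaxation time constant is ``tau = C * R_parallel``; with the default
device and actuator parameters tau is about two seconds, so stabilization
takes on the order of fifteen seconds.

Volume bookkeeping is exact by construction: the cumulative branch volumes
are integrated with the same RK4 stages as the pressure, so
``sum(cumulative volumes) + C*P + V0*beta*eps = 0`` holds to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .channel_mechanics import (
    UL,
    UM,
    ChannelGeometry,
    deform,
    hydraulic_resistance,
    resistance_per_length,
)
from .eec_pump import PumpConfig

__all__ = [
    "StrainWaveform",
    "ActuatorModel",
    "SimulationTrace",
    "DynamicRangeExceededError",
    "simulate",
    "per_cycle_pe",
    "mean_pe",
    "long_run_linearity",
    "LinearityResult",
]


class DynamicRangeExceededError(RuntimeError):
    """A meniscus left its observation channel: the device's dynamic range
    is exhausted and the lumped model no longer applies."""

    def __init__(self, side: str, time: float, position: float):
        self.side = side
        self.time = time
        self.position = position
        super().__init__(
            f"meniscus on the {side} side left the observation channel at "
            f"t={time:.3f} s (x={position / UM:.1f} um)"
        )


@dataclass(frozen=True)
class StrainWaveform:
    """Trapezoidal periodic strain: ramp up, hold, release, wait; repeated
    ``n_cycles`` times.  Zero-duration ramps are ideal steps.

    Defaults mirror the benchtop protocol: strain applied in one second,
    released in one second, with stabilization holds on either side.
    """

    amplitude: float
    ramp_time: float = 1.0
    hold_time: float = 15.0
    release_time: float = 1.0
    wait_time: float = 15.0
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        for name in ("ramp_time", "hold_time", "release_time", "wait_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")

    @property
    def period(self) -> float:
        return self.ramp_time + self.hold_time + self.release_time + self.wait_time

    def segments(self) -> list[tuple[float, float, float]]:
        """Per-cycle linear segments as (duration, eps_start, eps_end)."""
        e = self.amplitude
        return [
            (self.ramp_time, 0.0, e),
            (self.hold_time, e, e),
            (self.release_time, e, 0.0),
            (self.wait_time, 0.0, 0.0),
        ]


@dataclass(frozen=True)
class ActuatorModel:
    """Compliant strain-dilating actuator chamber.

    ``rest_volume`` V0 (uL), ``dilatation`` beta (relative capacity change
    per unit strain; stroke volume is ``V0 * beta * eps_max``), and
    ``compliance`` C (uL/Pa).  The defaults give a ~2 s time constant and a
    0.1 uL stroke at 5% strain with the default channel pair.
    """

    rest_volume: float = 1.0
    dilatation: float = 2.0
    compliance: float = 9.03e-3

    def __post_init__(self) -> None:
        if min(self.rest_volume, self.dilatation, self.compliance) <= 0:
            raise ValueError("all actuator parameters must be positive")

    def stroke_volume(self, amplitude: float) -> float:
        """Actuator stroke V_total (uL) for a given strain amplitude."""
        return self.rest_volume * self.dilatation * amplitude


@dataclass
class SimulationTrace:
    """Sampled state of a simulation run.

    Arrays are aligned with ``time``; pressures in Pa, meniscus positions
    (liquid-filled observation-channel lengths) in um, cumulative volumes
    pushed from the actuator into each branch in uL.
    """

    time: np.ndarray
    strain: np.ndarray
    pressure: np.ndarray
    x_left: np.ndarray
    x_right: np.ndarray
    cum_volume_left: np.ndarray
    cum_volume_right: np.ndarray
    period: float
    n_cycles: int
    stroke_volume: float  # uL
    har_side: str

    def conservation_error(self, actuator: ActuatorModel) -> float:
        """Max relative volume-balance violation over the trace."""
        total_out = (self.cum_volume_left + self.cum_volume_right) * UL
        stored = (
            actuator.compliance * UL * self.pressure
            + actuator.rest_volume * UL * actuator.dilatation * self.strain
        )
        scale = max(self.stroke_volume * UL, 1e-30)
        return float(np.max(np.abs(total_out + stored)) / scale)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "strain": self.strain,
                "pressure_pa": self.pressure,
                "x_left_um": self.x_left,
                "x_right_um": self.x_right,
                "cum_volume_left_uL": self.cum_volume_left,
                "cum_volume_right_uL": self.cum_volume_right,
            }
        )


def _branch_functions(
    config: PumpConfig,
) -> tuple[Callable[[float, float], float], Callable[[float, float], float], float, float]:
    """Build per-side resistance functions R(eps, x) in SI units and the
    observation cross-sectional areas (m^2; pumping-channel area for the
    continuous design, where resistance is x-independent)."""
    nu = config.fluid.poisson_ratio
    cache: dict[tuple[int, float], float] = {}

    def make(side_geom: ChannelGeometry, obs: ChannelGeometry | None):
        r_per_len = (
            resistance_per_length(obs, config.fluid) if obs is not None else 0.0
        )

        def resistance(eps: float, x: float) -> float:
            key = (id(side_geom), eps)
            r_pump = cache.get(key)
            if r_pump is None:
                g = deform(side_geom, eps, nu) if eps != 0.0 else side_geom
                r_pump = hydraulic_resistance(g, fluid=config.fluid)
                cache[key] = r_pump
            return r_pump + r_per_len * x

        area = (
            (obs.area if obs is not None else side_geom.area) * UM**2
        )
        return resistance, area

    r_left, a_left = make(config.left, config.left_observation)
    r_right, a_right = make(config.right, config.right_observation)
    return r_left, r_right, a_left, a_right


def simulate(
    config: PumpConfig,
    actuator: ActuatorModel,
    waveform: StrainWaveform,
    dt: float | None = None,
    settle_time: float = 0.0,
    initial_fill: float = 0.5,
) -> SimulationTrace:
    """Integrate the lumped network through the full waveform.

    Parameters
    ----------
    dt
        Fixed RK4 step (s); defaults to ``tau/100`` where ``tau`` is the
        rest-state parallel time constant.
    settle_time
        Extra zero-strain time appended after the last cycle so in-flight
        liquid can finish its transfer (attributed to the last cycle by
        :func:`per_cycle_pe`).
    initial_fill
        Initial liquid-filled fraction of each observation channel.

    Raises
    ------
    DynamicRangeExceededError
        If a meniscus leaves its observation channel (non-continuous
        design only).
    """
    r_left_fn, r_right_fn, a_left, a_right = _branch_functions(config)
    has_obs = config.left_observation is not None
    x_left0 = (
        config.left_observation.length * UM * initial_fill if has_obs else 0.0
    )
    x_right0 = (
        config.right_observation.length * UM * initial_fill if has_obs else 0.0
    )
    x_left_max = config.left_observation.length * UM if has_obs else np.inf
    x_right_max = config.right_observation.length * UM if has_obs else np.inf

    c_si = actuator.compliance * UL  # m^3/Pa
    v0_beta = actuator.rest_volume * UL * actuator.dilatation  # m^3 per strain

    if dt is None:
        r_par = 1.0 / (
            1.0 / r_left_fn(0.0, x_left0) + 1.0 / r_right_fn(0.0, x_right0)
        )
        dt = c_si * r_par / 100.0

    # state vector y = [P, x_L, x_R, V_L, V_R] (SI)
    def deriv(y: np.ndarray, eps: float, deps_dt: float) -> np.ndarray:
        p = y[0]
        r_l = r_left_fn(eps, y[1])
        r_r = r_right_fn(eps, y[2])
        q_l = p / r_l
        q_r = p / r_r
        return np.array(
            [
                (-v0_beta * deps_dt - p * (1.0 / r_l + 1.0 / r_r)) / c_si,
                q_l / a_left,
                q_r / a_right,
                q_l,
                q_r,
            ]
        )

    segments: list[tuple[float, float, float]] = []
    for _ in range(waveform.n_cycles):
        segments.extend(waveform.segments())
    if settle_time > 0.0:
        segments.append((settle_time, 0.0, 0.0))

    t = 0.0
    y = np.array([0.0, x_left0, x_right0, 0.0, 0.0])
    times = [0.0]
    strains = [0.0]
    states = [y.copy()]

    for duration, e0, e1 in segments:
        if duration == 0.0:
            if e1 != e0:  # ideal step: impulsive pressure jump
                y = y.copy()
                y[0] += -v0_beta * (e1 - e0) / c_si
                times.append(t)
                strains.append(e1)
                states.append(y.copy())
            continue
        deps_dt = (e1 - e0) / duration
        n_steps = max(1, int(np.ceil(duration / dt)))
        h = duration / n_steps
        for k in range(n_steps):
            eps_a = e0 + deps_dt * (k * h)
            eps_m = e0 + deps_dt * ((k + 0.5) * h)
            eps_b = e0 + deps_dt * ((k + 1) * h)
            k1 = deriv(y, eps_a, deps_dt)
            k2 = deriv(y + 0.5 * h * k1, eps_m, deps_dt)
            k3 = deriv(y + 0.5 * h * k2, eps_m, deps_dt)
            k4 = deriv(y + h * k3, eps_b, deps_dt)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if has_obs:
                if not 0.0 <= y[1] <= x_left_max:
                    raise DynamicRangeExceededError("left", t + (k + 1) * h, y[1])
                if not 0.0 <= y[2] <= x_right_max:
                    raise DynamicRangeExceededError("right", t + (k + 1) * h, y[2])
            times.append(t + (k + 1) * h)
            strains.append(eps_b)
            states.append(y.copy())
        t += duration

    arr = np.array(states)
    return SimulationTrace(
        time=np.array(times),
        strain=np.array(strains),
        pressure=arr[:, 0],
        x_left=arr[:, 1] / UM,
        x_right=arr[:, 2] / UM,
        cum_volume_left=arr[:, 3] / UL,
        cum_volume_right=arr[:, 4] / UL,
        period=waveform.period,
        n_cycles=waveform.n_cycles,
        stroke_volume=actuator.stroke_volume(waveform.amplitude),
        har_side=config.har_side,
    )


def _net_transport(trace: SimulationTrace) -> np.ndarray:
    """Cumulative HAR-to-LAR transported volume (uL) at each sample:
    half the difference of the branch cumulative volumes, signed positive
    toward the LAR side."""
    if trace.har_side == "left":
        diff = trace.cum_volume_right - trace.cum_volume_left
    else:
        diff = trace.cum_volume_left - trace.cum_volume_right
    return 0.5 * diff


def per_cycle_pe(trace: SimulationTrace, stroke_volume: float | None = None) -> np.ndarray:
    """Per-cycle pumping efficiency from a simulation trace.

    Cycle ``k``'s PE is the net HAR-to-LAR volume transported during that
    cycle's window divided by the stroke volume; any settle tail after the
    final cycle is attributed to the last cycle.
    """
    v_total = trace.stroke_volume if stroke_volume is None else stroke_volume
    if v_total <= 0:
        raise ValueError("stroke volume must be positive")
    net = _net_transport(trace)
    edges = np.concatenate(
        [
            np.searchsorted(
                trace.time, trace.period * np.arange(trace.n_cycles), side="left"
            ),
            [len(trace.time) - 1],
        ]
    )
    return np.diff(net[edges]) / v_total


def mean_pe(trace: SimulationTrace) -> float:
    """Whole-run pumping efficiency: total transported volume (including
    the settle tail) over total actuated volume."""
    net = _net_transport(trace)
    return float(net[-1] - net[0]) / (trace.stroke_volume * trace.n_cycles)


@dataclass(frozen=True)
class LinearityResult:
    """Cumulative net-transport series at cycle ends and its linear fit."""

    cycle: np.ndarray
    cumulative_volume: np.ndarray  # uL, HAR -> LAR
    slope: float
    intercept: float
    r_squared: float
    increments: np.ndarray = field(default=None)  # type: ignore[assignment]


def long_run_linearity(
    config: PumpConfig,
    actuator: ActuatorModel,
    waveform: StrainWaveform,
    n_actuations: int,
    dt: float | None = None,
) -> LinearityResult:
    """Cumulative displaced volume over many actuations and its linearity.

    With observation channels the growing meniscus imbalance perturbs the
    per-cycle increment, curving the series; the continuous design (no
    observation channel, position-independent resistances) repeats the same
    cycle and stays linear, so its linear-fit R^2 is at least as high.
    """
    from scipy.stats import linregress

    wf = StrainWaveform(
        amplitude=waveform.amplitude,
        ramp_time=waveform.ramp_time,
        hold_time=waveform.hold_time,
        release_time=waveform.release_time,
        wait_time=waveform.wait_time,
        n_cycles=n_actuations,
    )
    trace = simulate(config, actuator, wf, dt=dt)
    net = _net_transport(trace)
    idx = np.searchsorted(
        trace.time, wf.period * np.arange(1, n_actuations + 1), side="left"
    )
    idx = np.minimum(idx, len(trace.time) - 1)
    cycles = np.arange(1, n_actuations + 1)
    cumulative = net[idx] - net[0]
    fit = linregress(cycles, cumulative)
    return LinearityResult(
        cycle=cycles,
        cumulative_volume=cumulative,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        increments=np.diff(np.concatenate([[0.0], cumulative])),
    )
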