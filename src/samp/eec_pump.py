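"""Quasi-static equivalent-electrical-circuit (EEC) model of the pump.

The actuator is a cyclic flow source; the two asymmetric pumping channels
(APCs) are parallel resistors.  During the strained half-cycle the stroke
volume ``V_total`` is drawn through the *strained* resistances; on release
the same volume returns through the *rest* resistances.  The per-cycle net
transport from the high-AR (HAR) branch toward the low-AR (LAR) branch,
divided by the stroke volume, is the pumping efficiency

    PE = R'_LAR / (R'_LAR + R'_HAR)  -  R_LAR / (R_LAR + R_HAR)

i.e. the difference of the HAR branch's current-divider fractions between
the strained and relaxed phases (the branch with the *lower* resistance
carries the *larger* flow, so the cross resistance sits in the numerator).
PE is independent of ``V_total`` and vanishes only when the two aspect
ratios are equal.

Observation channels, when present, add series resistance held at the rest
value on both branches (they sit outside the strained footprint); being
identical on both sides they only dilute the asymmetry and reduce |PE|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .channel_mechanics import (
    ChannelGeometry,
    FluidProperties,
    approx_deformed_resistance,
    deformed_resistance,
    gamma_factor,
    hydraulic_resistance,
)

__all__ = [
    "PumpConfig",
    "CycleResult",
    "flow_split",
    "branch_resistances",
    "pumping_efficiency",
    "net_volume_per_cycle",
    "pe_sweep",
]

ResistanceModel = Literal["exact", "approximate"]


@dataclass(frozen=True)
class PumpConfig:
    """Two pumping-channel branches, optional observation channels, and the
    actuator stroke volume.

    The "HAR side" is the branch with the larger aspect ratio.  Observation
    channels are added in series to their branch at rest-value resistance.
    """

    left: ChannelGeometry
    right: ChannelGeometry
    stroke_volume: float = 0.1  # uL displaced per half-cycle
    fluid: FluidProperties = FluidProperties()
    left_observation: ChannelGeometry | None = None
    right_observation: ChannelGeometry | None = None

    def __post_init__(self) -> None:
        if self.stroke_volume <= 0:
            raise ValueError("stroke_volume must be positive")
        if (self.left_observation is None) != (self.right_observation is None):
            raise ValueError(
                "observation channels must be present on both sides or neither"
            )

    @property
    def har_side(self) -> str:
        """'left' or 'right': the branch with the larger aspect ratio.

        Ties (equal ARs) report 'left'; PE is zero there so the label is
        immaterial.
        """
        return (
            "right"
            if self.right.aspect_ratio > self.left.aspect_ratio
            else "left"
        )

    def swapped(self) -> "PumpConfig":
        """The same pump with left and right branches exchanged."""
        return PumpConfig(
            left=self.right,
            right=self.left,
            stroke_volume=self.stroke_volume,
            fluid=self.fluid,
            left_observation=self.right_observation,
            right_observation=self.left_observation,
        )


@dataclass(frozen=True)
class CycleResult:
    """Per-branch volumes for one strain cycle (uL) and the cycle PE.

    ``strained`` volumes are drawn from each branch into the actuator while
    the strain is held; ``released`` volumes are pushed back on release.
    ``net`` is the signed volume gained by each branch over the full cycle:
    positive on the LAR side, negative on the HAR side, summing to zero.
    """

    strained: dict[str, float]
    released: dict[str, float]
    net: dict[str, float]
    pe: float


def flow_split(r_a: float, r_b: float, q_total: float) -> tuple[float, float]:
    """Split a total flow between two parallel resistances.

    Physical current divider: ``Q_a = R_b / (R_a + R_b) * Q_total`` — the
    lower-resistance branch carries the larger flow.  ``Q_a + Q_b`` equals
    ``Q_total`` exactly.
    """
    if r_a <= 0 or r_b <= 0:
        raise ValueError("resistances must be positive")
    q_a = r_b / (r_a + r_b) * q_total
    return q_a, q_total - q_a


def branch_resistances(
    config: PumpConfig, strain: float, model: ResistanceModel = "exact"
) -> tuple[dict[str, float], dict[str, float]]:
    """Rest and strained total branch resistances (Pa*s/m^3).

    Pumping channels are deformed by the strain (exact or first-order
    model); observation channels contribute their full rest resistance on
    both phases.
    """
    deformed = (
        deformed_resistance if model == "exact" else approx_deformed_resistance
    )
    rest: dict[str, float] = {}
    strained: dict[str, float] = {}
    for side, pump_ch, obs_ch in (
        ("left", config.left, config.left_observation),
        ("right", config.right, config.right_observation),
    ):
        r_obs = (
            hydraulic_resistance(obs_ch, fluid=config.fluid)
            if obs_ch is not None
            else 0.0
        )
        rest[side] = hydraulic_resistance(pump_ch, fluid=config.fluid) + r_obs
        strained[side] = deformed(pump_ch, strain, fluid=config.fluid) + r_obs
    return rest, strained


def _har_fraction(resistances: dict[str, float], har_side: str) -> float:
    """Flow fraction through the HAR branch (cross-resistance divider)."""
    other = "right" if har_side == "left" else "left"
    return resistances[other] / (resistances["left"] + resistances["right"])


def pumping_efficiency(
    config: PumpConfig, strain: float, model: ResistanceModel = "exact"
) -> float:
    """Signed pumping efficiency for one strain cycle.

    Positive PE means net transport from the HAR branch toward the LAR
    branch (the only direction the ASID mechanism produces); PE = 0 when
    the two aspect ratios are equal, whatever the areas.
    """
    if strain < 0:
        raise ValueError("strain must be non-negative")
    rest, strained = branch_resistances(config, strain, model)
    har = config.har_side
    return _har_fraction(strained, har) - _har_fraction(rest, har)


def net_volume_per_cycle(
    config: PumpConfig, strain: float, model: ResistanceModel = "exact"
) -> CycleResult:
    """Per-branch displaced volumes for one strain cycle.

    Each branch's net volume is ``(rest fraction - strained fraction) *
    V_total``: the HAR branch loses ``PE * V_total`` and the LAR branch
    gains it, so the two nets are equal and opposite.
    """
    rest, strained = branch_resistances(config, strain, model)
    v = config.stroke_volume

    def frac(res: dict[str, float], side: str) -> float:
        # fraction of the total flow carried by `side` (cross divider)
        other = "right" if side == "left" else "left"
        return res[other] / (res["left"] + res["right"])

    strained_v = {s: frac(strained, s) * v for s in ("left", "right")}
    released_v = {s: frac(rest, s) * v for s in ("left", "right")}
    net = {s: released_v[s] - strained_v[s] for s in ("left", "right")}
    return CycleResult(
        strained=strained_v,
        released=released_v,
        net=net,
        pe=pumping_efficiency(config, strain, model),
    )


def _rest_resistance_by_ar(ar: np.ndarray, area: float) -> np.ndarray:
    """Normalized rest resistance for unit-length channels of given AR and
    cross-sectional area (vectorized)."""
    h = np.sqrt(ar * area)
    w = np.sqrt(area / ar)
    a = np.minimum(w, h)
    b = np.maximum(w, h)
    return 1.0 / ((1.0 - 0.63 * a / b) * a**3 * b)


def _strained_factor(
    ar: np.ndarray, strain: float, model: ResistanceModel, nu: float
) -> np.ndarray:
    """R'/R ratio per aspect ratio (vectorized over ar)."""
    g = gamma_factor(strain, nu)
    if model == "approximate":
        low = (1.0 - 0.63 * ar) / (1.0 - 0.63 * g * ar) / (1.0 - strain / 2.0)
        high = (
            (1.0 - 0.63 / ar)
            / (1.0 - 0.63 / (g * ar))
            / (1.0 + 2.5 * strain)
        )
        return np.where(ar <= 1.0, low, high)
    # exact: deform dims, re-apply the duct formula
    h = np.sqrt(ar)
    w = 1.0 / h
    wp = w * (1.0 + strain)
    hp = h * (1.0 - nu * strain)
    a0, b0 = np.minimum(w, h), np.maximum(w, h)
    a1, b1 = np.minimum(wp, hp), np.maximum(wp, hp)
    r0 = 1.0 / ((1.0 - 0.63 * a0 / b0) * a0**3 * b0)
    r1 = 1.0 / ((1.0 - 0.63 * a1 / b1) * a1**3 * b1)
    return r1 / r0


def pe_sweep(
    ar_lo: float = 0.1,
    ar_hi: float = 10.0,
    n_grid: int = 101,
    strain: float = 0.1,
    area_policy: str = "equal",
    area_factor: float = 1.5,
    model: ResistanceModel = "approximate",
    poisson_ratio: float = 0.5,
) -> pd.DataFrame:
    """Signed-PE heat-map grid over left/right aspect-ratio pairs.

    The grid is log-spaced over ``[ar_lo, ar_hi]`` on both axes (the default
    101 points over a symmetric decade range sample both the antisymmetric
    corners and the AR = 1 diagonal exactly).  Sign convention: positive PE
    for transport from the right branch toward the left, so the grid is
    antisymmetric under transposition when areas are equal and zero on the
    equal-AR diagonal.

    ``area_policy='equal'`` gives both sides the same cross-sectional area;
    ``'right_scaled'`` multiplies the right side's width and height by
    ``area_factor`` (default 1.5).

    Returns a long-format DataFrame with columns ``ar_left``, ``ar_right``,
    ``pe``.
    """
    if not 0 < ar_lo < ar_hi:
        raise ValueError("require 0 < ar_lo < ar_hi")
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    if area_policy not in ("equal", "right_scaled"):
        raise ValueError(f"unknown area_policy {area_policy!r}")
    ar = np.logspace(np.log10(ar_lo), np.log10(ar_hi), n_grid)
    area_left = 1.0
    area_right = area_factor**2 if area_policy == "right_scaled" else 1.0

    r_left = _rest_resistance_by_ar(ar, area_left)  # (n,)
    r_right = _rest_resistance_by_ar(ar, area_right)
    factor = _strained_factor(ar, strain, model, poisson_ratio)

    rl = r_left[:, None] * np.ones_like(ar)[None, :]
    rr = np.ones_like(ar)[:, None] * r_right[None, :]
    rlp = (r_left * factor)[:, None] * np.ones_like(ar)[None, :]
    rrp = np.ones_like(ar)[:, None] * (r_right * factor)[None, :]

    # fraction through the RIGHT branch = R_left / (R_left + R_right);
    # PE > 0 <=> strained phase draws extra from the right => right-to-left.
    pe = rlp / (rlp + rrp) - rl / (rl + rr)

    ar_l, ar_r = np.meshgrid(ar, ar, indexing="ij")
    return pd.DataFrame(
        {"ar_left": ar_l.ravel(), "ar_right": ar_r.ravel(), "pe": pe.ravel()}
    )
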