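"""Deformation and hydraulic resistance of rectangular microchannels.

A channel of width ``w`` and height ``h`` (aspect ratio ``AR = h/w``)
embedded in an elastomer and strained *orthogonally to its axis* deforms as

    w' = w (1 + eps)        h' = h (1 - nu * eps)

so the aspect ratio scales by ``gamma = (1 - nu*eps) / (1 + eps)``.  For an
incompressible elastomer (``nu = 0.5``) high-AR channels (AR > 1) become
*less* resistive under tension while low-AR channels (AR < 1) become *more*
resistive — the asymmetry in strain-induced deformation (ASID) that drives
valveless pumping.

The hydraulic resistance uses the standard single-term lubrication
approximation for a rectangular duct, written with ``a = min(w, h)`` and
``b = max(w, h)`` so one formula covers both orientations:

    R = 12 * mu * L / ((1 - 0.63 * a / b) * a**3 * b)

The ``normalized`` variant drops the ``12 * mu * L`` prefactor (resistance
per unit length and viscosity), which is all that pumping-efficiency ratios
ever need.

Units: lengths in micrometres, viscosity in mPa*s; non-normalized
resistances are returned in SI (Pa*s/m^3).  All unit conversions live in
this module (`UM`, `MPAS`, `UL`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

__all__ = [
    "UM",
    "MPAS",
    "UL",
    "ChannelGeometry",
    "FluidProperties",
    "SmallStrainValidityWarning",
    "gamma_factor",
    "deform",
    "hydraulic_resistance",
    "deformed_resistance",
    "approx_deformed_resistance",
]

# Unit conversions to SI: micrometre, millipascal-second, microlitre.
UM = 1e-6  # m
MPAS = 1e-3  # Pa*s
UL = 1e-9  # m^3

#: Strain above which the first-order deformed-resistance expansion is
#: flagged as unreliable.
SMALL_STRAIN_LIMIT = 0.15


class SmallStrainValidityWarning(UserWarning):
    """Raised when the first-order resistance expansion is used outside
    its stated validity range (|eps| > 0.15)."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel cross-section and length, in micrometres."""

    width: float
    height: float
    length: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.length <= 0:
            raise ValueError(
                f"channel dimensions must be positive, got "
                f"w={self.width}, h={self.height}, L={self.length}"
            )

    @property
    def aspect_ratio(self) -> float:
        """AR = h/w; HAR means AR > 1, LAR means AR < 1."""
        return self.height / self.width

    @property
    def area(self) -> float:
        """Cross-sectional area in um^2."""
        return self.width * self.height

    @classmethod
    def from_aspect_ratio(
        cls, aspect_ratio: float, area: float = 1.0, length: float = 1.0
    ) -> "ChannelGeometry":
        """Build a channel with a given AR and cross-sectional area.

        ``h = sqrt(AR * area)``, ``w = sqrt(area / AR)``.
        """
        if aspect_ratio <= 0 or area <= 0:
            raise ValueError("aspect_ratio and area must be positive")
        height = (aspect_ratio * area) ** 0.5
        width = (area / aspect_ratio) ** 0.5
        return cls(width=width, height=height, length=length)


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid dynamic viscosity (mPa*s) and elastomer Poisson ratio.

    Defaults: an ionic working liquid of ~28 mPa*s in an incompressible
    (nu = 0.5) elastomer.
    """

    viscosity: float = 28.0
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


def gamma_factor(strain: float, poisson_ratio: float = 0.5) -> float:
    """Aspect-ratio scale factor ``gamma = (1 - nu*eps) / (1 + eps)``.

    The deformed aspect ratio is ``AR' = gamma * AR``.
    """
    if strain <= -1:
        raise ValueError("strain must exceed -1")
    return (1.0 - poisson_ratio * strain) / (1.0 + strain)


def deform(
    geometry: ChannelGeometry, strain: float, poisson_ratio: float = 0.5
) -> ChannelGeometry:
    """Apply an orthogonal engineering strain to a channel cross-section.

    ``w' = w(1 + eps)``, ``h' = h(1 - nu*eps)``; the length is unchanged
    because the strain axis is orthogonal to the channel elongation.

    Raises
    ------
    ValueError
        If the strain is non-physical (eps <= -1) or would collapse the
        channel (h' <= 0 or w' <= 0).
    """
    if strain <= -1:
        raise ValueError("strain must exceed -1")
    if not 0.0 <= poisson_ratio <= 0.5:
        raise ValueError("poisson_ratio must lie in [0, 0.5]")
    new_w = geometry.width * (1.0 + strain)
    new_h = geometry.height * (1.0 - poisson_ratio * strain)
    if new_w <= 0 or new_h <= 0:
        raise ValueError(
            f"strain {strain} collapses the channel (w'={new_w}, h'={new_h})"
        )
    return replace(geometry, width=new_w, height=new_h)


def hydraulic_resistance(
    geometry: ChannelGeometry,
    fluid: FluidProperties | None = None,
    normalized: bool = False,
) -> float:
    """Hydraulic resistance of a rectangular channel.

    Single-term lubrication form with ``a = min(w, h)``, ``b = max(w, h)``:
    symmetric under swapping w and h, strictly decreasing in both.

    Parameters
    ----------
    geometry
        Channel dimensions in micrometres.
    fluid
        Required unless ``normalized=True``.
    normalized
        If True, return ``1 / ((1 - 0.63 a/b) a^3 b)`` in 1/um^4 —
        resistance per unit length and viscosity.  Otherwise return
        ``12 mu L`` times that, in Pa*s/m^3.
    """
    a = min(geometry.width, geometry.height)
    b = max(geometry.width, geometry.height)
    base = 1.0 / ((1.0 - 0.63 * a / b) * a**3 * b)
    if normalized:
        return base
    if fluid is None:
        fluid = FluidProperties()
    # convert 1/um^4 -> 1/m^4, lengths um -> m, viscosity mPa*s -> Pa*s
    return 12.0 * (fluid.viscosity * MPAS) * (geometry.length * UM) * base / UM**4


def resistance_per_length(
    geometry: ChannelGeometry, fluid: FluidProperties | None = None
) -> float:
    """Resistance per unit liquid-filled length, in Pa*s/m^4."""
    if fluid is None:
        fluid = FluidProperties()
    base = hydraulic_resistance(geometry, normalized=True)
    return 12.0 * (fluid.viscosity * MPAS) * base / UM**4


def deformed_resistance(
    geometry: ChannelGeometry,
    strain: float,
    fluid: FluidProperties | None = None,
    normalized: bool = False,
) -> float:
    """Exact strained resistance: deform the cross-section, then apply the
    rectangular-duct formula to the deformed dimensions."""
    nu = fluid.poisson_ratio if fluid is not None else 0.5
    return hydraulic_resistance(
        deform(geometry, strain, nu), fluid=fluid, normalized=normalized
    )


def approx_deformed_resistance(
    geometry: ChannelGeometry,
    strain: float,
    fluid: FluidProperties | None = None,
    normalized: bool = False,
) -> float:
    """First-order (small-strain) strained resistance.

    For AR <= 1 (low aspect ratio; AR exactly 1 routes through this branch
    by convention — both branches give the identical value there):

        R' = R * (1 - 0.63 AR) / (1 - 0.63 gamma AR) / (1 - eps/2)

    and for AR > 1 (high aspect ratio):

        R' = R * (1 - 0.63/AR) / (1 - 0.63/(gamma AR)) / (1 + 5 eps/2)

    Under tension the low-AR resistance rises and the high-AR resistance
    falls — the ASID asymmetry.  A :class:`SmallStrainValidityWarning` is
    emitted for |eps| > 0.15.
    """
    if abs(strain) > SMALL_STRAIN_LIMIT:
        warnings.warn(
            f"first-order resistance expansion used at |eps|={abs(strain):.3g} "
            f"> {SMALL_STRAIN_LIMIT}",
            SmallStrainValidityWarning,
            stacklevel=2,
        )
    nu = fluid.poisson_ratio if fluid is not None else 0.5
    g = gamma_factor(strain, nu)
    ar = geometry.aspect_ratio
    rest = hydraulic_resistance(geometry, fluid=fluid, normalized=normalized)
    if ar <= 1.0:
        factor = (1.0 - 0.63 * ar) / (1.0 - 0.63 * g * ar) / (1.0 - strain / 2.0)
    else:
        factor = (
            (1.0 - 0.63 / ar) / (1.0 - 0.63 / (g * ar)) / (1.0 + 2.5 * strain)
        )
    return rest * factor
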