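"""Resultant skin strain along a sensor orientation.

Digital-image-correlation (DIC) post-processing yields, at each surface
point, the first and second principal Lagrangian strains: magnitudes
``M1, M2`` and orthogonal unit directions ``u1, u2``.  A pump mounted on
the skin responds to the strain component along its own axis ``s`` (the
line orthogonal to its reservoirs), so the scalar that predicts pumping is
the resultant strain

    eps_R = M1 * (u1 . s) + M2 * (u2 . s)

summed with signed projections by default — compressive (negative)
resultants are physical and show up as negative pumping.  An
absolute-value variant (`rectify=True`) is available.  The device-level
predictor is the unweighted mean of ``eps_R`` over the grid points inside
the sensor footprint, ``<eps_R>``.

Field files are point-list CSVs (x_mm, y_mm, m1, m2, angle1_deg); the
second principal direction is the perpendicular of the first, so
orthogonality is exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "StrainField",
    "SensorFootprint",
    "resultant_strain",
    "mean_resultant_strain",
]

_UNIT_TOL = 1e-6


def _as_unit(v: np.ndarray, name: str) -> np.ndarray:
    """Normalize direction vectors, warning if they deviate from unit
    length by more than 1e-6."""
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError(f"{name} contains zero vectors")
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        warnings.warn(
            f"{name} deviates from unit length by up to "
            f"{float(np.max(np.abs(norms - 1.0))):.2e}; normalizing",
            stacklevel=3,
        )
    return v / norms


@dataclass
class StrainField:
    """Principal-strain point cloud: N points with coordinates (mm),
    principal magnitudes M1/M2 and orthogonal unit directions u1/u2."""

    points: np.ndarray  # (N, 2) mm
    m1: np.ndarray  # (N,)
    m2: np.ndarray  # (N,)
    u1: np.ndarray  # (N, 2)
    u2: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        self.u1 = _as_unit(np.atleast_2d(self.u1), "u1")
        self.u2 = _as_unit(np.atleast_2d(self.u2), "u2")
        n = len(self.points)
        for name in ("m1", "m2", "u1", "u2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match points")
        dots = np.abs(np.einsum("ij,ij->i", self.u1, self.u2))
        if np.any(dots > 1e-6):
            raise ValueError(
                "principal directions are not orthogonal "
                f"(max |u1.u2| = {float(dots.max()):.2e})"
            )

    @classmethod
    def from_angles(
        cls,
        points: np.ndarray,
        m1: np.ndarray,
        m2: np.ndarray,
        angle1_deg: np.ndarray,
    ) -> "StrainField":
        """Build a field from the first principal angle; the second
        direction is its perpendicular (rotated +90 degrees)."""
        theta = np.deg2rad(np.asarray(angle1_deg, dtype=float))
        u1 = np.column_stack([np.cos(theta), np.sin(theta)])
        u2 = np.column_stack([-np.sin(theta), np.cos(theta)])
        return cls(points=points, m1=m1, m2=m2, u1=u1, u2=u2)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StrainField":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        required = {"x_mm", "y_mm", "m1", "m2", "angle1_deg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"strain-field CSV missing columns {sorted(missing)}")
        return cls.from_angles(
            points=df[["x_mm", "y_mm"]].to_numpy(),
            m1=df["m1"].to_numpy(),
            m2=df["m2"].to_numpy(),
            angle1_deg=df["angle1_deg"].to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        angle1 = np.rad2deg(np.arctan2(self.u1[:, 1], self.u1[:, 0]))
        pd.DataFrame(
            {
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "m1": self.m1,
                "m2": self.m2,
                "angle1_deg": angle1,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SensorFootprint:
    """Sensor location, outline and orientation on the skin.

    The outline is a circle (``radius``, mm) or a polygon (``vertices``,
    (K, 2) mm, relative to the absolute frame).  ``orientation_deg`` is the
    sensor axis — the line orthogonal to the pump reservoirs — measured
    from the +x axis.  Points on the outline count as inside.
    """

    center: tuple[float, float]
    orientation_deg: float
    radius: float | None = None
    vertices: tuple[tuple[float, float], ...] | None = None
    name: str = "sensor"

    def __post_init__(self) -> None:
        if (self.radius is None) == (self.vertices is None):
            raise ValueError("specify exactly one of radius or vertices")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.vertices is not None and len(self.vertices) < 3:
            raise ValueError("polygon outline needs at least 3 vertices")

    @property
    def orientation(self) -> np.ndarray:
        """Unit vector of the sensor axis."""
        theta = np.deg2rad(self.orientation_deg)
        return np.array([np.cos(theta), np.sin(theta)])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed outline."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.radius is not None:
            d2 = np.sum((pts - np.asarray(self.center)) ** 2, axis=1)
            return d2 <= self.radius**2 * (1 + 1e-12)
        poly = Polygon(self.vertices)
        return np.array([poly.covers(Point(p)) for p in pts])


def resultant_strain(
    m1: np.ndarray,
    u1: np.ndarray,
    m2: np.ndarray,
    u2: np.ndarray,
    s: np.ndarray,
    rectify: bool = False,
) -> np.ndarray:
    """Resultant strain along the sensor axis, per point.

    ``eps_R = M1 (u1 . s) + M2 (u2 . s)`` with signed projections; with
    ``rectify=True`` the absolute projections are summed instead.  The
    result is invariant under a common rotation of all vectors.
    """
    u1 = _as_unit(np.atleast_2d(u1), "u1")
    u2 = _as_unit(np.atleast_2d(u2), "u2")
    s = _as_unit(np.asarray(s, dtype=float), "s")
    p1 = np.asarray(m1, dtype=float) * (u1 @ s)
    p2 = np.asarray(m2, dtype=float) * (u2 @ s)
    if rectify:
        return np.abs(p1) + np.abs(p2)
    return p1 + p2


def mean_resultant_strain(
    field: StrainField, footprint: SensorFootprint, rectify: bool = False
) -> float:
    """Unweighted mean of ``eps_R`` over grid points inside the footprint.

    Raises
    ------
    ValueError
        If no grid point falls inside the footprint (names the footprint).
    """
    mask = footprint.contains(field.points)
    if not np.any(mask):
        raise ValueError(
            f"no strain-field points inside footprint {footprint.name!r}"
        )
    eps = resultant_strain(
        field.m1[mask],
        field.u1[mask],
        field.m2[mask],
        field.u2[mask],
        footprint.orientation,
        rectify=rectify,
    )
    return float(np.mean(eps))
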