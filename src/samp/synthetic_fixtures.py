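"""Seeded generators for every measured input the pipeline consumes.

Real runs of the device produce (a) meniscus-displacement series read off
chip photographs and (b) DIC principal-strain fields of the skin around the
sensor.  Neither can be shipped, so these generators emulate them:

* :func:`make_meniscus_series` — a linear displaced-volume trend whose
  slope is the configured true pumping efficiency times the stroke volume,
  with i.i.d. Gaussian read-off noise per record, mirrored with opposite
  signs on the HAR and LAR sides.
* :func:`make_strain_field` — a smooth Gaussian bump of principal-strain
  magnitude on a regular grid with fixed principal directions, the shape a
  localized skin stretch produces.

What they do not emulate: non-uniform load profiles, capillary-pressure
fluctuations, drift between sets — the noise is white and the trend exactly
linear, so recovery tests probe the estimators, not skin biomechanics.

All generators are deterministic under a fixed seed, and their outputs
round-trip bit-identically through the module CSV readers.  Default scales
follow the wrist-scale measurements (rates of order 0.01 uL per actuation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment_analysis import MeniscusSeries
from .strain_projection import StrainField

__all__ = ["FixtureSpec", "make_meniscus_series", "make_strain_field"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic measurement campaign.

    Meniscus-series block: ``pe_true`` (dimensionless), ``v_total`` (uL),
    ``noise_sigma`` (uL, per-record read-off noise), ``n_actuations``.
    Strain-field block: grid ``extent`` (mm, square, centred at 0) and
    ``grid_step`` (mm), bump ``center`` (mm), ``width`` (mm, Gaussian
    sigma), peak magnitudes ``peak_m1``/``peak_m2`` and the first principal
    angle ``angle1_deg``.
    """

    seed: int = 0
    pe_true: float = 0.02
    v_total: float = 0.1
    noise_sigma: float = 0.002
    n_actuations: int = 10
    chip_id: str = "synthetic-1"
    extent: float = 40.0
    grid_step: float = 1.0
    bump_center: tuple[float, float] = (0.0, 0.0)
    bump_width: float = 8.0
    peak_m1: float = 0.08
    peak_m2: float = 0.03
    angle1_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_actuations < 1:
            raise ValueError("n_actuations must be at least 1")
        if self.v_total <= 0 or self.bump_width <= 0 or self.grid_step <= 0:
            raise ValueError("v_total, bump_width and grid_step must be positive")


def make_meniscus_series(spec: FixtureSpec) -> MeniscusSeries:
    """Synthetic per-actuation displaced-volume series for both sides.

    The true cumulative transported volume after ``n`` actuations is
    ``pe_true * v_total * n``; the LAR record is ``+that + noise`` and the
    HAR record ``-that + noise`` with independent Gaussian noise per
    record, so the expected PE slope recovered by the fit equals
    ``pe_true``.
    """
    rng = np.random.default_rng(spec.seed)
    n = np.arange(1, spec.n_actuations + 1)
    truth = spec.pe_true * spec.v_total * n
    rows = []
    for side, sign in (("LAR", 1.0), ("HAR", -1.0)):
        noise = rng.normal(0.0, spec.noise_sigma, size=n.size)
        rows.append(
            pd.DataFrame(
                {
                    "chip_id": spec.chip_id,
                    "side": side,
                    "actuation": n,
                    "volume_uL": sign * truth + noise,
                }
            )
        )
    return MeniscusSeries(
        data=pd.concat(rows, ignore_index=True),
        v_total=spec.v_total,
        strain=None,
        metadata={"seed": str(spec.seed), "pe_true": repr(spec.pe_true)},
    )


def make_strain_field(spec: FixtureSpec) -> StrainField:
    """Synthetic principal-strain field: a Gaussian magnitude bump on a
    regular grid with spatially constant principal directions.

    Both magnitudes peak at ``bump_center`` and decay with the shared
    Gaussian width, so a footprint centred on the bump with its axis along
    the first principal direction reads ``<eps_R>`` close to ``peak_m1``,
    while a footprint far from the bump reads approximately zero.
    """
    half = spec.extent / 2.0
    axis = np.arange(-half, half + spec.grid_step / 2.0, spec.grid_step)
    xx, yy = np.meshgrid(axis, axis)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    d2 = np.sum((pts - np.asarray(spec.bump_center)) ** 2, axis=1)
    envelope = np.exp(-d2 / (2.0 * spec.bump_width**2))
    return StrainField.from_angles(
        points=pts,
        m1=spec.peak_m1 * envelope,
        m2=spec.peak_m2 * envelope,
        angle1_deg=np.full(pts.shape[0], spec.angle1_deg),
    )
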