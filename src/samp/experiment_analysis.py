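"""Measurement reductions: PE slopes, pumping rates, correlations, boxes.

The pump encodes activity as cumulative meniscus displacement, so every
experiment reduces to a displaced-volume series versus actuation count.
The pumping efficiency is the ordinary-least-squares slope of
``V_net / V_total`` against actuation count (HAR-side records are
sign-flipped before pooling, since the two sides displace equal and
opposite volumes); pumping rates divide per-set displacement slopes by the
repetitions per set; device-level predictions are compared with measured
rates through the Pearson correlation; exercise panels are summarized by
quartile box statistics with min/max whiskers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeniscusSeries",
    "FitResult",
    "CorrelationResult",
    "BoxStats",
    "fit_pe",
    "pumping_rate",
    "correlate",
    "box_stats",
]

SIDES = ("HAR", "LAR")


@dataclass
class MeniscusSeries:
    """Per-actuation displaced-volume records for one chip.

    ``data`` columns: ``chip_id``, ``side`` (HAR|LAR), ``actuation``
    (non-negative, strictly increasing per side), ``volume_uL`` (signed
    displaced volume; LAR positive, HAR negative under normal pumping).
    ``v_total`` (uL) and ``strain`` are metadata; without ``v_total`` only
    raw-volume analysis is available.
    """

    data: pd.DataFrame
    v_total: float | None = None
    strain: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chip_id", "side", "actuation", "volume_uL"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"series missing columns {sorted(missing)}")
        bad = set(self.data["side"].unique()) - set(SIDES)
        if bad:
            raise ValueError(f"unknown side labels {sorted(bad)}; expected {SIDES}")
        if (self.data["actuation"] < 0).any():
            raise ValueError("actuation counts must be non-negative")
        for side, grp in self.data.groupby("side"):
            acts = grp["actuation"].to_numpy()
            if np.any(np.diff(acts) <= 0):
                raise ValueError(
                    f"actuation counts must be strictly increasing per side "
                    f"(side {side})"
                )
        if self.v_total is not None and self.v_total <= 0:
            raise ValueError("v_total must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeniscusSeries":
        """Read the measurement CSV; ``# key: value`` header comment lines
        carry the metadata (v_total_uL, strain, seed, ...)."""
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        v_total = float(meta["v_total_uL"]) if "v_total_uL" in meta else None
        strain = float(meta["strain"]) if "strain" in meta else None
        return cls(data=df, v_total=v_total, strain=strain, metadata=meta)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.v_total is not None:
                fh.write(f"# v_total_uL: {self.v_total!r}\n")
            if self.strain is not None:
                fh.write(f"# strain: {self.strain!r}\n")
            for key, value in self.metadata.items():
                if key not in ("v_total_uL", "strain"):
                    fh.write(f"# {key}: {value}\n")
            self.data.to_csv(fh, index=False)

    def normalized(self) -> pd.DataFrame:
        """Pooled (actuation, V_net/V_total) points with HAR sign-flipped,
        so both sides estimate the same positive transport."""
        if self.v_total is None:
            raise ValueError("v_total metadata required for normalized series")
        df = self.data.copy()
        sign = np.where(df["side"] == "HAR", -1.0, 1.0)
        df["v_net_ratio"] = sign * df["volume_uL"] / self.v_total
        return df


class FitResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


class CorrelationResult(NamedTuple):
    r: float
    slope: float
    intercept: float
    r_squared: float


class BoxStats(NamedTuple):
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float


def _ols(x: np.ndarray, y: np.ndarray) -> FitResult:
    if np.ptp(x) == 0:
        raise ValueError("x values are constant; cannot fit a slope")
    if np.ptp(y) == 0:
        # flat series: slope 0 with R^2 defined as 0 by convention
        return FitResult(0.0, float(y[0]), 0.0)
    fit = stats.linregress(x, y)
    return FitResult(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def fit_pe(series: MeniscusSeries) -> FitResult:
    """Pumping efficiency as the OLS slope of V_net/V_total vs actuations.

    Requires at least 3 pooled points and the ``v_total`` metadata.
    """
    df = series.normalized()
    if len(df) < 3:
        raise ValueError("need at least 3 points to fit a PE slope")
    return _ols(df["actuation"].to_numpy(float), df["v_net_ratio"].to_numpy(float))


def pumping_rate(
    set_displacements: Sequence[float], reps_per_set: int
) -> FitResult:
    """Pumping rate per actuation from per-set cumulative displacements.

    ``set_displacements`` is the cumulative displaced volume (uL) recorded
    after each set of ``reps_per_set`` repetitions.  The rate is the OLS
    slope across sets divided by the repetitions per set (a single set
    falls back to displacement / reps).  Returns (rate, intercept, R^2).
    """
    if reps_per_set <= 0:
        raise ValueError("reps_per_set must be positive")
    v = np.asarray(list(set_displacements), dtype=float)
    if v.size == 0:
        raise ValueError("set_displacements is empty")
    if v.size == 1:
        return FitResult(float(v[0]) / reps_per_set, 0.0, 1.0)
    sets = np.arange(1, v.size + 1, dtype=float)
    if np.ptp(v) == 0 and v[0] == 0:
        return FitResult(0.0, 0.0, 0.0)
    fit = _ols(sets, v)
    return FitResult(fit.slope / reps_per_set, fit.intercept, fit.r_squared)


def correlate(rates: Sequence[float], strains: Sequence[float]) -> CorrelationResult:
    """Pearson correlation (and OLS line) of pumping rates against the
    mean resultant strain per device; for the simple regression the line's
    R^2 equals r^2."""
    x = np.asarray(list(strains), dtype=float)
    y = np.asarray(list(rates), dtype=float)
    if x.size != y.size:
        raise ValueError("rates and strains must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    return CorrelationResult(r, float(fit.slope), float(fit.intercept), r**2)


def box_stats(values: Sequence[float]) -> BoxStats:
    """Five-number box summary: median, quartiles by linear interpolation
    between order statistics, whiskers at the sample min and max."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("values is empty")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return BoxStats(float(med), float(q1), float(q3), float(v.min()), float(v.max()))
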