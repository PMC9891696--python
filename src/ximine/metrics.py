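"""Adaptive-laboratory-evolution and fermentation arithmetic.

Small pure functions over optical-density and sugar time series:

* generations per serial transfer, ``log2(OD_final / OD_initial)``;
* xylose utilization rate over the first day, ``(c_0h - c_24h) / 24`` in
  g/liter per hour;
* fractional product yield, ``product / (consumed glucose + consumed
  xylose) / 0.51`` where 0.51 g/g is the theoretical ethanol yield on sugar;
* dry cell weight from OD600 with the linear coefficient 0.34 g DCW per OD
  unit;
* specific consumption/production rates normalized by time-averaged biomass.

Rates are reported positive for consumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

THEORETICAL_YIELD_FACTOR = 0.51  # g ethanol per g sugar
DCW_PER_OD = 0.34  # g dry cell weight per OD600 unit


@dataclass(frozen=True)
class MetricsConstants:
    theoretical_yield_factor: float = THEORETICAL_YIELD_FACTOR
    dcw_per_od: float = DCW_PER_OD

    def __post_init__(self) -> None:
        if self.theoretical_yield_factor <= 0 or self.dcw_per_od <= 0:
            raise ValueError("constants must be positive")


@dataclass(frozen=True)
class AleTransfer:
    """One serial-transfer growth cycle."""

    od_initial: float
    od_final: float
    duration_h: float = 24.0

    def __post_init__(self) -> None:
        if self.od_initial <= 0 or self.od_final <= 0:
            raise ValueError("optical densities must be positive")


def generations(transfer: AleTransfer) -> float:
    """Doublings in one transfer: log2(OD_final / OD_initial)."""
    return math.log2(transfer.od_final / transfer.od_initial)


def total_generations(transfers: Sequence[AleTransfer]) -> float:
    return sum(generations(t) for t in transfers)


def xylose_rate(c0: float, c24: float) -> float:
    """Xylose utilization rate (g/liter/h) from the 0 h and 24 h samples."""
    if c0 < 0 or c24 < 0:
        raise ValueError("concentrations must be nonnegative")
    return (c0 - c24) / 24.0


def product_yield(product: float, consumed_glucose: float, consumed_xylose: float,
                  constants: MetricsConstants = MetricsConstants()) -> float:
    """Fraction of the theoretical yield achieved."""
    total_sugar = consumed_glucose + consumed_xylose
    if total_sugar <= 0:
        raise ValueError("no sugar consumed")
    if product < 0:
        raise ValueError("product must be nonnegative")
    return product / total_sugar / constants.theoretical_yield_factor


def dcw_from_od(od: float, constants: MetricsConstants = MetricsConstants()) -> float:
    """Dry cell weight (g/liter) from OD600."""
    if od < 0:
        raise ValueError("OD must be nonnegative")
    return constants.dcw_per_od * od


class FermentationSeries:
    """Time-ordered fermentation samples; any analyte may be missing.

    Backed by a DataFrame with columns time_h, od600, glucose, xylose,
    ethanol (blank cells = missing).
    """

    ANALYTES = ("od600", "glucose", "xylose", "ethanol")

    def __init__(self, frame: pd.DataFrame) -> None:
        if "time_h" not in frame.columns:
            raise ValueError("series needs a time_h column")
        frame = frame.sort_values("time_h").reset_index(drop=True)
        times = frame["time_h"].to_numpy(dtype=float)
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        for col in self.ANALYTES:
            if col in frame.columns and (frame[col].dropna() < 0).any():
                raise ValueError(f"negative values in {col}")
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str) -> "FermentationSeries":
        return cls(pd.read_csv(path))

    def value_at(self, analyte: str, time_h: float) -> float:
        row = self.frame[self.frame["time_h"] == time_h]
        if row.empty:
            raise KeyError(f"no sample at {time_h} h")
        val = row.iloc[0][analyte]
        if pd.isna(val):
            raise KeyError(f"{analyte} missing at {time_h} h")
        return float(val)


def specific_rate(series: FermentationSeries, analyte: str,
                  window: tuple[float, float],
                  constants: MetricsConstants = MetricsConstants(),
                  biomass_mean: str = "trapezoidal") -> float:
    """Specific consumption rate, g per g DCW per hour, over a time window.

    The biomass denominator is the time-weighted mean DCW over the window
    (trapezoidal integration of 0.34 x OD600 over time; ``biomass_mean=
    "endpoint"`` uses the plain mean of the two endpoint DCWs instead).
    Positive values mean consumption.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive width")
    c0 = series.value_at(analyte, t0)
    c1 = series.value_at(analyte, t1)
    sub = series.frame[(series.frame["time_h"] >= t0) & (series.frame["time_h"] <= t1)]
    od = sub["od600"]
    if od.isna().any():
        raise ValueError("od600 missing inside the window")
    times = sub["time_h"].to_numpy(dtype=float)
    dcw = np.array([dcw_from_od(x, constants) for x in od.to_numpy(dtype=float)])
    if biomass_mean == "trapezoidal":
        mean_dcw = float(np.trapezoid(dcw, times) / (t1 - t0))
    elif biomass_mean == "endpoint":
        mean_dcw = float((dcw[0] + dcw[-1]) / 2.0)
    else:
        raise ValueError(f"unknown biomass_mean {biomass_mean!r}")
    if mean_dcw <= 0:
        raise ValueError("zero biomass in the window")
    return (c0 - c1) / mean_dcw / (t1 - t0)
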