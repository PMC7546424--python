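"""Raw assay readouts to normalized biological rates.

Acetylene reduction (ARA): nitrogenase reduces acetylene to ethylene in
place of N2; measured ethylene is converted to an N2-fixation rate with
a 4:1 molar factor (4 mol ethylene per mol N2) and normalized per cell
or per nmol total chlorophyll.

ROS kinetics: DCFH-DA oxidation produces fluorescent DCF; the ROS
production rate is the ordinary least-squares slope of blank-corrected
fluorescence against time, expressed in arbitrary units per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AraMeasurement",
    "AraRate",
    "FluorescenceSeries",
    "RosRate",
    "ara_to_n2",
    "ros_slope",
]

ACETYLENE_TO_N2 = 4.0  # mol ethylene per mol N2 fixed


@dataclass(frozen=True)
class AraMeasurement:
    """One acetylene-reduction incubation.

    normalizer is a cell count (rates in pmol N2 cell^-1 h^-1 scale) or
    nmol total chlorophyll (nmol N2 nmol Chl^-1 h^-1).
    """

    ethylene_nmol: float
    incubation_h: float
    sample_volume_ml: float
    normalizer: float
    conversion_ratio: float = ACETYLENE_TO_N2
    detection_limit_nmol: float = 0.0

    def __post_init__(self):
        for name in ("ethylene_nmol", "incubation_h", "sample_volume_ml", "conversion_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.normalizer == 0:
            raise ValueError("normalizer must be non-zero")


@dataclass(frozen=True)
class AraRate:
    rate_per_normalizer_per_h: float
    rate_nmol_per_ml_per_h: float  # per-ml intermediate, the bulk rate
    undetectable: bool


def ara_to_n2(m: AraMeasurement) -> AraRate:
    """Convert an ARA measurement to an N2-fixation rate.

    The bulk rate is ethylene / incubation / ratio / volume
    (nmol N2 ml^-1 h^-1); the normalized rate multiplies back by volume
    and divides by the normalizer, so the volume bookkeeping cancels for
    whole-sample normalizers.  Ethylene at or below the detection limit
    flags the rate as undetectable (reported NaN).
    """
    undetectable = m.ethylene_nmol <= m.detection_limit_nmol
    n2_per_h = m.ethylene_nmol / m.incubation_h / m.conversion_ratio
    per_ml = n2_per_h / m.sample_volume_ml
    rate = float("nan") if undetectable else n2_per_h / m.normalizer
    return AraRate(
        rate_per_normalizer_per_h=rate,
        rate_nmol_per_ml_per_h=float("nan") if undetectable else per_ml,
        undetectable=undetectable,
    )


@dataclass(frozen=True)
class FluorescenceSeries:
    """Fluorescence kinetics with a matched cell-free blank."""

    times_min: tuple
    au: tuple
    blank_times_min: tuple
    blank_au: tuple
    cells: float

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.au, dtype=float)
        bt = np.asarray(self.blank_times_min, dtype=float)
        by = np.asarray(self.blank_au, dtype=float)
        if t.size != y.size or bt.size != by.size:
            raise ValueError("times and fluorescence lengths must match")
        if t.size < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(t) < 0) or np.any(np.diff(bt) < 0):
            raise ValueError("times must be non-decreasing")
        if self.cells <= 0:
            raise ValueError("cells must be positive")


@dataclass(frozen=True)
class RosRate:
    au_per_cell_per_min: float
    negative: bool

    @property
    def au_per_cell_per_h(self) -> float:
        return self.au_per_cell_per_min * 60.0


def _ols_slope(t, y):
    t = np.asarray(t, dtype=float)
    if np.allclose(t, t[0]):
        raise ValueError("singular regression: all times equal")
    return float(stats.linregress(t, np.asarray(y, dtype=float)).slope)


def ros_slope(fs: FluorescenceSeries) -> RosRate:
    """Blank-corrected OLS fluorescence slope per cell.

    When signal and blank share a time grid the blank is subtracted
    pointwise before the regression; otherwise the blank's own fitted
    slope is subtracted from the signal slope.  Negative slopes are
    reported as-is with a flag.
    """
    t = np.asarray(fs.times_min, dtype=float)
    bt = np.asarray(fs.blank_times_min, dtype=float)
    if t.size == bt.size and np.allclose(t, bt):
        slope = _ols_slope(t, np.asarray(fs.au) - np.asarray(fs.blank_au))
    else:
        slope = _ols_slope(t, fs.au) - _ols_slope(bt, fs.blank_au)
    per_cell = slope / fs.cells
    return RosRate(au_per_cell_per_min=per_cell, negative=per_cell < 0)
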