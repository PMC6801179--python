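"""qPCR calibration fitting and species quantification.

A species-specific single-copy-gene assay yields threshold cycles (Ct)
that fall linearly with log10 template: Ct = intercept + slope *
log10(cells).  The calibration is fitted by OLS on standards counted by
flow cytometry (so loads are in fluorescence-unit equivalents, FU);
samples are quantified by back-transforming each replicate Ct and
reporting mean +/- sd of the per-replicate cell counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CalibrationCurve:
    species: str
    slope: float  # Ct per log10 cells; negative for a working assay
    intercept: float
    r_squared: float
    n_points: int
    efficiency: float  # 10^(-1/slope) - 1; 1.0 is a perfect doubling
    ct_range: tuple[float, float]


def fit_calibration(
    cells: list[float], ct: list[float], species: str = ""
) -> CalibrationCurve:
    """OLS fit of Ct against log10(cells) over >= 3 standards."""
    x = np.log10(np.asarray(cells, dtype=float))
    y = np.asarray(ct, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("at least 3 distinct standard concentrations are required")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        species=species,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=len(x),
        efficiency=10 ** (-1.0 / res.slope) - 1.0,
        ct_range=(float(y.min()), float(y.max())),
    )


@dataclass
class QuantResult:
    species: str
    cells_per_replicate: list[float]
    mean_cells: float
    sd_cells: float
    n_replicates: int
    extrapolated: bool

    def formatted(self) -> str:
        """Mean +/- sd in the a x 10^b notation of a product-quantification table."""
        return f"{_sci(self.mean_cells)} ± {_sci(self.sd_cells)}"


def _sci(x: float) -> str:
    if x == 0:
        return "0"
    exp = math.floor(math.log10(abs(x)))
    mant = x / 10**exp
    return f"{mant:.1f} × 10^{exp}"


def quantify(
    ct_values: list[float],
    curve: CalibrationCurve,
    dilution: float = 1.0,
    grams: float = 1.0,
) -> QuantResult:
    """Back-transform replicate Ct values to cell loads.

    cells = 10^((Ct - intercept)/slope) per replicate, scaled by the
    dilution factor and divided by the sample mass; the reported sd is
    the sd of the per-replicate back-transformed counts (back-transform
    then average, not the reverse).  Ct values more than 2 cycles
    outside the calibrated range trigger an extrapolation warning.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; quantification undefined")
    ct = np.asarray(ct_values, dtype=float)
    lo, hi = curve.ct_range
    extrapolated = bool(np.any((ct < lo - 2) | (ct > hi + 2)))
    if extrapolated:
        warnings.warn("Ct outside calibrated range (+/- 2 cycles); extrapolating")
    cells = 10 ** ((ct - curve.intercept) / curve.slope) * dilution / grams
    sd = float(cells.std(ddof=1)) if len(cells) > 1 else 0.0
    return QuantResult(
        species=curve.species,
        cells_per_replicate=cells.tolist(),
        mean_cells=float(cells.mean()),
        sd_cells=sd,
        n_replicates=len(cells),
        extrapolated=extrapolated,
    )
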