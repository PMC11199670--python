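"""Concentration calibration and limit-of-detection estimation.

A dilution series of integrated band intensities (counts cm^-1 s^-1)
versus concentration (mM) is fitted by ordinary least squares; the slope
is the sensitivity of the band.  The limit of detection is the smallest
concentration at which the series, read from zero upwards, can no longer
be fitted with a horizontal line - formalised as an extra-sum-of-squares
F-test between the horizontal (intercept-only) and straight-line models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationSeries",
    "CalibrationModel",
    "fit_calibration",
    "estimate_lod",
    "intensity_to_concentration",
]


@dataclass
class CalibrationSeries:
    """Replicate band intensities measured across a dilution series.

    ``table`` has columns ``concentration`` (mM), ``replicate`` (int) and
    ``intensity`` (counts cm^-1 s^-1, already dwell-normalised).
    """

    table: pd.DataFrame
    dwell: float
    band: str = "1401"
    spectra: list | None = None

    def __post_init__(self) -> None:
        required = {"concentration", "replicate", "intensity"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"series table missing columns {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("calibration series is empty")
        if (self.table["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def from_arrays(cls, concentrations, intensities, dwell: float,
                    band: str = "1401", spectra=None) -> "CalibrationSeries":
        conc = np.asarray(concentrations, dtype=float)
        inten = np.asarray(intensities, dtype=float)
        if conc.shape != inten.shape:
            raise ValueError("concentration/intensity arrays must align")
        rep = np.zeros(conc.size, dtype=int)
        counts: dict[float, int] = {}
        for i, c in enumerate(conc):
            rep[i] = counts.get(c, 0)
            counts[c] = rep[i] + 1
        table = pd.DataFrame({"concentration": conc, "replicate": rep,
                              "intensity": inten})
        return cls(table, dwell=dwell, band=band, spectra=spectra)

    @property
    def concentrations(self) -> np.ndarray:
        return self.table["concentration"].to_numpy()

    @property
    def intensities(self) -> np.ndarray:
        return self.table["intensity"].to_numpy()

    def min_replicates(self) -> int:
        return int(self.table.groupby("concentration").size().min())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["dwell"] = self.dwell
        out["band"] = self.band
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CalibrationSeries":
        df = pd.read_csv(path)
        dwell = float(df["dwell"].iloc[0]) if "dwell" in df else 1.0
        band = str(df["band"].iloc[0]) if "band" in df else "1401"
        return cls(df[["concentration", "replicate", "intensity"]],
                   dwell=dwell, band=band)


@dataclass
class CalibrationModel:
    """Linear intensity-concentration calibration.

    ``sensitivity`` is the slope in counts cm^-1 s^-1 mM^-1;
    ``lod`` stays ``None`` until :func:`estimate_lod` defines it.
    """

    sensitivity: float
    intercept: float
    r_squared: float
    lod: float | None = None
    alpha: float = 0.05
    band: str = "1401"
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "lod": self.lod,
            "alpha": self.alpha,
            "band": self.band,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(sensitivity=float(d["sensitivity"]),
                   intercept=float(d["intercept"]),
                   r_squared=float(d["r_squared"]),
                   lod=None if d.get("lod") is None else float(d["lod"]),
                   alpha=float(d.get("alpha", 0.05)),
                   band=str(d.get("band", "1401")))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2 with the conventions: a perfect fit gives
    r^2 = 1 and a series with zero total variance gives r^2 = 0."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("need at least two distinct concentrations to fit")
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = float(((y - ym) ** 2).sum())
    ss_res = float(((y - slope * x - intercept) ** 2).sum())
    if ss_tot <= 0:
        r2 = 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return slope, intercept, r2


def fit_calibration(series: CalibrationSeries, alpha: float = 0.05,
                    through_origin: bool = False) -> CalibrationModel:
    """Ordinary least squares of intensity on concentration, pooling
    replicates.  The intercept is retained by default."""
    x = series.concentrations
    y = series.intensities
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct concentrations to fit")
    if through_origin:
        slope = float((x * y).sum() / (x * x).sum())
        intercept = 0.0
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float(((y - slope * x) ** 2).sum())
        r2 = 0.0 if ss_tot <= 0 else max(0.0, 1.0 - ss_res / ss_tot)
    else:
        slope, intercept, r2 = _ols(x, y)
    return CalibrationModel(sensitivity=slope, intercept=intercept,
                            r_squared=r2, alpha=alpha, band=series.band,
                            meta={"n": int(len(y)), "dwell": series.dwell})


def _horizontal_vs_line_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Extra-sum-of-squares F-test of the straight line against the
    horizontal (mean-only) model."""
    n = y.size
    ss_h = float(((y - y.mean()) ** 2).sum())
    slope, intercept, _ = _ols(x, y)
    ss_l = float(((y - slope * x - intercept) ** 2).sum())
    df_resid = n - 2
    if df_resid <= 0:
        return 1.0
    if ss_l <= 0:
        # the line is exact; any reduction from the horizontal model wins
        return 0.0 if ss_h > 0 else 1.0
    f = (ss_h - ss_l) / (ss_l / df_resid)
    return float(stats.f.sf(f, 1, df_resid))


def estimate_lod(series: CalibrationSeries, alpha: float = 0.05) -> float | None:
    """Limit of detection by the horizontal-line criterion.

    Scanning prefixes of the concentration series from zero upwards, the
    LOD is the smallest concentration whose prefix rejects the horizontal
    model in favour of a straight line at level ``alpha``.  Returns
    ``None`` when no prefix rejects (the series is flat throughout).
    """
    if series.min_replicates() < 2:
        raise ValueError(
            "LOD estimation needs >= 2 replicates per concentration so "
            "that residual variance is estimable"
        )
    x_all = series.concentrations
    y_all = series.intensities
    levels = np.unique(x_all)  # sorted ascending, ties pooled
    if levels.size < 2:
        raise ValueError("need at least two distinct concentrations")
    for j in range(1, levels.size):
        mask = x_all <= levels[j]
        p = _horizontal_vs_line_pvalue(x_all[mask], y_all[mask])
        if p < alpha:
            return float(levels[j])
    return None


def intensity_to_concentration(intensity, model: CalibrationModel):
    """Invert the calibration: (I - intercept) / sensitivity, in mM.

    Negative outputs are returned unclipped so that below-LOD mass stays
    visible in concentration histograms.
    """
    if model.sensitivity == 0:
        raise ValueError("calibration sensitivity must be non-zero")
    if model.sensitivity < 0:
        raise ValueError("calibration sensitivity must be positive")
    conc = (np.asarray(intensity, dtype=float) - model.intercept) / model.sensitivity
    return float(conc) if conc.ndim == 0 else conc
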