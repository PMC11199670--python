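"""Per-pixel fumarate quantification of hyperspectral maps.

Two routes convert spectra to concentration: the AUC route (despike,
iterative polynomial baseline, flat-baseline band integral, calibration
inversion) and a Gaussian-fit route (peak fitted over a local window
without polynomial baseline subtraction; the fitted height is the
measure).  Both express results in mM via a calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .calibrate import CalibrationModel, intensity_to_concentration
from .core import (
    BASELINE_WINDOW,
    INTEGRATION_WINDOW,
    SpectralMap,
    Spectrum,
    window_mask,
)
from .preprocess import (
    BaselineParams,
    band_auc_map,
    iterative_baseline_matrix,
    despike_map,
)

__all__ = [
    "ConcentrationMap",
    "ConcentrationHistogram",
    "concentration_map_auc",
    "gaussian_peak_quantify",
    "fit_height_calibration",
    "band_intensity_map",
    "concentration_histogram",
]


@dataclass
class ConcentrationMap:
    """Per-pixel fumarate concentrations (mM) with a validity mask."""

    values: np.ndarray            # (H, W), mM; may be negative (below LOD)
    mask: np.ndarray              # (H, W) bool, True = valid pixel
    lod: float | None = None
    method: str = "auc"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("values and mask must share one (H, W) shape")
        if self.lod is not None and self.lod < 0:
            raise ValueError("lod must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def crop(self, rows: slice, cols: slice) -> "ConcentrationMap":
        return ConcentrationMap(self.values[rows, cols],
                                self.mask[rows, cols], lod=self.lod,
                                method=self.method, meta=dict(self.meta))


@dataclass
class ConcentrationHistogram:
    """Relative occurrence of concentrations, normalised per scan."""

    bin_edges: np.ndarray
    occurrence: np.ndarray        # sums to 1 over bins
    scan_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "occurrence": self.occurrence,
        })


def concentration_map_auc(smap: SpectralMap, model: CalibrationModel,
                          baseline: BaselineParams = BaselineParams(),
                          despike: bool = True) -> ConcentrationMap:
    """AUC-route concentration map.

    Per pixel: cosmic-ray removal, iterative polynomial baseline
    (default order 4, 7 iterations, tolerance 15 counts), flat-baseline
    band integral over 1399-1419 cm^-1 (baseline window 1324-1379), then
    inversion through the calibration.  No smoothing is applied.
    """
    wn = smap.wavenumbers
    window_mask(wn, BASELINE_WINDOW)
    window_mask(wn, INTEGRATION_WINDOW)
    if despike:
        smap = despike_map(smap)
    h, w, c = smap.counts.shape
    flat = smap.counts.reshape(-1, c)
    base = iterative_baseline_matrix(flat, wn, baseline.order,
                                     baseline.iterations, baseline.tolerance)
    corrected = (flat - base).reshape(h, w, c)
    intensity = band_auc_map(smap, corrected=corrected)
    conc = intensity_to_concentration(intensity, model)
    return ConcentrationMap(conc, np.ones((h, w), dtype=bool),
                            lod=model.lod, method="auc",
                            meta={"baseline": (baseline.order,
                                               baseline.iterations,
                                               baseline.tolerance)})


def _gauss_lin(x, height, center, sigma, offset, slope):
    return offset + slope * (x - x.mean()) \
        + height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gaussian_peak_quantify(spec: Spectrum,
                           window: tuple[float, float] = (1380.0, 1420.0),
                           height_calibration: float | None = None,
                           center_bounds: tuple[float, float] = (1395.0, 1407.0),
                           sigma_bounds: tuple[float, float] = (2.0, 12.0)
                           ) -> float | None:
    """Gaussian + linear-background fit of the 1401 cm^-1 band.

    Returns fitted height / ``height_calibration`` (mM), or the raw
    height in counts s^-1 when no calibration is given.  Fit failures
    return ``None`` (never zero) so they can be masked.
    """
    mask = window_mask(spec.wavenumbers, window)
    x = spec.wavenumbers[mask]
    y = spec.counts[mask] / spec.dwell
    h0 = max(float(y.max() - np.median(y)), 1e-6)
    p0 = [h0, 1401.0, 4.0, float(np.median(y)), 0.0]
    lower = [0.0, center_bounds[0], sigma_bounds[0], -np.inf, -np.inf]
    upper = [np.inf, center_bounds[1], sigma_bounds[1], np.inf, np.inf]
    try:
        popt, _ = curve_fit(_gauss_lin, x, y, p0=p0, bounds=(lower, upper),
                            maxfev=5000)
    except (RuntimeError, ValueError):
        return None
    height = float(popt[0])
    if height_calibration is None:
        return height
    return height / height_calibration


def concentration_map_gauss(smap: SpectralMap, height_per_mm: float,
                            window: tuple[float, float] = (1380.0, 1420.0),
                            despike: bool = True) -> ConcentrationMap:
    """Gaussian-fit-route concentration map.

    Each pixel's 1401 cm^-1 band is fitted without polynomial baseline
    subtraction; fit failures are masked, not zero-filled.
    """
    from .preprocess import despike_map as _despike
    if despike:
        smap = _despike(smap)
    h, w = smap.shape
    values = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            mm = gaussian_peak_quantify(smap.pixel(r, c), window=window,
                                        height_calibration=height_per_mm)
            if mm is not None:
                values[r, c] = mm
                mask[r, c] = True
    return ConcentrationMap(values, mask, method="gauss",
                            meta={"window": window})


def fit_height_calibration(spectra: list[Spectrum], concs,
                           window: tuple[float, float] = (1380.0, 1420.0)
                           ) -> float:
    """Height-per-mM calibration for the Gaussian route, regressed from
    known-concentration spectra (e.g. a synthetic dilution series)."""
    concs = np.asarray(list(concs), dtype=float)
    heights = np.array([
        gaussian_peak_quantify(s, window=window) or np.nan for s in spectra
    ])
    ok = np.isfinite(heights)
    if ok.sum() < 2 or np.unique(concs[ok]).size < 2:
        raise ValueError("need fits at >= 2 distinct concentrations")
    x, y = concs[ok], heights[ok]
    return float((x * y).sum() / (x * x).sum())


def band_intensity_map(smap: SpectralMap, band_center: float = 1130.0,
                       half_width: float = 10.0) -> np.ndarray:
    """Per-pixel flat-baseline AUC of an arbitrary band (counts cm^-1 s^-1).

    The flat baseline is the mean count level over two flanking strips of
    the same half-width on either side of the integration window.  Used
    for tissue outlines and masks.
    """
    wn = smap.wavenumbers
    integ = (band_center - half_width, band_center + half_width)
    int_mask = window_mask(wn, integ)
    left = window_mask(wn, (band_center - 3 * half_width,
                            band_center - half_width - smap.wavenumbers[1]
                            + smap.wavenumbers[0]))
    right = window_mask(wn, (band_center + half_width + smap.wavenumbers[1]
                             - smap.wavenumbers[0],
                             band_center + 3 * half_width))
    flank = left | right
    flat = smap.counts[..., flank].mean(axis=-1, keepdims=True)
    area = np.trapezoid(smap.counts[..., int_mask] - flat, wn[int_mask],
                        axis=-1)
    return area / smap.dwell


def concentration_histogram(cmap: ConcentrationMap, bin_width: float = 5.0,
                            scan_id: str = "") -> ConcentrationHistogram:
    """Histogram of valid-pixel concentrations, normalised by pixel count.

    Bin edges are anchored at 0 mM so that negative (below-LOD) values
    fall into well-defined bins rather than being dropped.
    """
    vals = cmap.valid_values()
    if vals.size == 0:
        raise ValueError("concentration map has no valid pixels")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, edges = np.histogram(vals, bins=edges)
    occurrence = hist / vals.size
    return ConcentrationHistogram(edges, occurrence, scan_id=scan_id)
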