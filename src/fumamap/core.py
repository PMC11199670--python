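"""Core containers for Raman spectra and hyperspectral maps.

Everything downstream operates on two containers: a :class:`Spectrum`
(one wavenumber axis + one counts vector + acquisition metadata) and a
:class:`SpectralMap` (an H x W grid of spectra sharing one axis).  All
intensities are raw detector counts; integrated band intensities are
reported in counts * cm^-1 * s^-1, i.e. normalised by the dwell time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

# Default spectral sampling: fingerprint region, 1 cm^-1 grid.  The
# instrument resolution at 532 nm is ~3.6 cm^-1, so 1 cm^-1 sampling
# oversamples it, matching typical CCD binning.
AXIS_START = 400.0
AXIS_STOP = 1800.0
AXIS_STEP = 1.0

#: Flat-baseline window preceding the fumarate band (cm^-1).
BASELINE_WINDOW = (1324.0, 1379.0)
#: Integration window around the 1401 cm^-1 fumarate band (cm^-1).
INTEGRATION_WINDOW = (1399.0, 1419.0)
#: Fingerprint region used for AUC normalisation (cm^-1).
FINGERPRINT_REGION = (500.0, 1800.0)

#: Calibration sensitivity of the 1401 cm^-1 band, counts cm^-1 s^-1 mM^-1.
DEFAULT_SENSITIVITY = 19.2
#: Experimental noise floor (1 sigma, counts) at the reference dwell.
DEFAULT_NOISE_FLOOR = 7.5
#: Reference dwell time (s) at which the noise floor applies.
REFERENCE_DWELL = 0.3


def default_axis(start: float = AXIS_START, stop: float = AXIS_STOP,
                 step: float = AXIS_STEP) -> np.ndarray:
    """Return the default strictly increasing wavenumber axis (cm^-1)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def validate_axis(wavenumbers: np.ndarray) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size < 2:
        raise ValueError("wavenumber axis must be 1-D with at least 2 points")
    d = np.diff(wn)
    if not np.all(d > 0):
        idx = int(np.argmax(d <= 0))
        raise ValueError(
            f"wavenumber axis must be strictly increasing; "
            f"violation at index {idx + 1} ({wn[idx]} -> {wn[idx + 1]})"
        )
    return wn


def window_mask(wavenumbers: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of channels inside a closed interval [lo, hi]."""
    lo, hi = window
    if hi < lo:
        raise ValueError(f"window {window} has hi < lo")
    mask = (wavenumbers >= lo) & (wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"window {window} contains no channels of axis "
            f"[{wavenumbers[0]}, {wavenumbers[-1]}]"
        )
    return mask


@dataclass
class Spectrum:
    """A single Raman spectrum.

    Parameters
    ----------
    wavenumbers : array, cm^-1, strictly increasing
    counts : array, detector counts per channel
    dwell : acquisition (integration) time per spectrum, seconds
    power : incident laser power, mW (optional, informational)
    meta : free-form provenance tags
    """

    wavenumbers: np.ndarray
    counts: np.ndarray
    dwell: float
    power: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = validate_axis(self.wavenumbers)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.wavenumbers.shape:
            raise ValueError(
                f"counts length {self.counts.shape} does not match axis "
                f"length {self.wavenumbers.shape}"
            )
        if not self.dwell > 0:
            raise ValueError("dwell must be positive")

    def with_counts(self, counts: np.ndarray) -> "Spectrum":
        return replace(self, counts=np.asarray(counts, dtype=float))

    def copy(self) -> "Spectrum":
        return replace(self, counts=self.counts.copy(), meta=dict(self.meta))


@dataclass
class SpectralMap:
    """An H x W hyperspectral Raman image sharing one wavenumber axis.

    ``counts`` has shape (H, W, channels); pixels are indexed (row, col)
    from the top-left, 0-based.  ``step_um`` is the spatial step in
    micrometres.
    """

    wavenumbers: np.ndarray
    counts: np.ndarray
    step_um: float
    dwell: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = validate_axis(self.wavenumbers)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("map counts must have shape (H, W, channels)")
        if self.counts.shape[2] != self.wavenumbers.size:
            raise ValueError("map channel count does not match axis length")
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValueError("map must contain at least one pixel")
        if not self.dwell > 0:
            raise ValueError("dwell must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[0], self.counts.shape[1]

    @property
    def n_pixels(self) -> int:
        h, w = self.shape
        return h * w

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.counts[row, col],
                        dwell=self.dwell, meta={"pixel": (row, col)})

    def flat(self) -> np.ndarray:
        """(n_pixels, channels) view of the counts cube, row-major."""
        return self.counts.reshape(-1, self.counts.shape[2])

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.wavenumbers, self.flat().mean(axis=0),
                        dwell=self.dwell, meta={"derived": "scan-average"})

    def crop(self, rows: slice, cols: slice) -> "SpectralMap":
        return SpectralMap(self.wavenumbers, self.counts[rows, cols],
                           step_um=self.step_um, dwell=self.dwell,
                           meta=dict(self.meta))
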