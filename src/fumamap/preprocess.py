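"""Spectrum-level conditioning.

Despiking, iterative polynomial baseline estimation, flat-baseline band
integration, fingerprint-AUC normalisation, scan mean-centering,
Savitzky-Golay smoothing (display only) and mean difference spectra.

The quantification chain is: despike -> iterative polynomial baseline
(order 4, 7 iterations, tolerance 15 counts) -> flat local baseline
(mean counts over 1324-1379 cm^-1) -> trapezoidal integration over
1399-1419 cm^-1 -> divide by dwell.  No smoothing is ever applied inside
this chain; Savitzky-Golay is exposed for display only because smoothing
biases extracted concentrations depending on the window choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    BASELINE_WINDOW,
    FINGERPRINT_REGION,
    INTEGRATION_WINDOW,
    SpectralMap,
    Spectrum,
    window_mask,
)

__all__ = [
    "BaselineParams",
    "remove_cosmic_rays",
    "iterative_polynomial_baseline",
    "iterative_baseline_matrix",
    "band_auc",
    "normalize_fingerprint_auc",
    "mean_center_scan",
    "savgol_smooth",
    "mean_difference_spectrum",
]


@dataclass(frozen=True)
class BaselineParams:
    """Iterative polynomial baseline parameters.

    ``tolerance`` is in counts and was chosen in the source protocol as
    twice the experimental noise floor.
    """

    order: int = 4
    iterations: int = 7
    tolerance: float = 15.0

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("polynomial order must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


# ---------------------------------------------------------------------------
# Cosmic-ray removal
# ---------------------------------------------------------------------------

def _spike_flags(counts: np.ndarray, z_threshold: float,
                 min_height: float) -> np.ndarray:
    """Flag single/few-channel spikes via a robust residual criterion.

    The residual of each channel against a 5-point running median is
    scored with a modified z-score (median/MAD).  Genuine Raman bands are
    several channels wide and survive the median filter; cosmic rays are
    1-2 channels wide and do not.  ``min_height`` (counts) is an absolute
    floor so that smooth noiseless spectra, where the MAD collapses to
    ~0, are never flagged.
    """
    n = counts.size
    # running median, window 5, edges handled by shrinking the window
    from scipy.ndimage import median_filter
    med = median_filter(counts, size=5, mode="nearest")
    resid = counts - med
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sigma = mad / 0.6745
    threshold = max(z_threshold * robust_sigma, min_height)
    flags = resid > threshold  # spikes are positive excursions
    return flags if flags.shape == (n,) else flags.reshape(n)


def remove_cosmic_rays(spec: Spectrum, z_threshold: float = 8.0,
                       min_height: float = 30.0) -> Spectrum:
    """Replace cosmic-ray spikes by the mean of their nearest clean neighbours.

    Channels not flagged as spikes are returned bit-identical.  Applying
    the filter twice is idempotent.
    """
    counts = spec.counts
    if counts.size < 5:
        raise ValueError("despiking needs at least 5 channels")
    flags = _spike_flags(counts, z_threshold, min_height)
    if not flags.any():
        return spec
    cleaned = counts.copy()
    clean_idx = np.flatnonzero(~flags)
    if clean_idx.size == 0:  # pathological: everything flagged
        return spec
    for i in np.flatnonzero(flags):
        left = clean_idx[clean_idx < i]
        right = clean_idx[clean_idx > i]
        vals = []
        if left.size:
            vals.append(counts[left[-1]])
        if right.size:
            vals.append(counts[right[0]])
        cleaned[i] = np.mean(vals)
    out = spec.with_counts(cleaned)
    out.meta = dict(spec.meta, despiked_channels=int(flags.sum()))
    return out


def despike_map(smap: SpectralMap, z_threshold: float = 8.0,
                min_height: float = 30.0) -> SpectralMap:
    """Apply :func:`remove_cosmic_rays` to every pixel of a map."""
    cube = smap.counts.copy()
    h, w, _ = cube.shape
    for r in range(h):
        for c in range(w):
            flags = _spike_flags(cube[r, c], z_threshold, min_height)
            if flags.any():
                spec = Spectrum(smap.wavenumbers, cube[r, c], dwell=smap.dwell)
                cube[r, c] = remove_cosmic_rays(
                    spec, z_threshold, min_height).counts
    return SpectralMap(smap.wavenumbers, cube, step_um=smap.step_um,
                       dwell=smap.dwell, meta=dict(smap.meta))


# ---------------------------------------------------------------------------
# Iterative polynomial baseline (Lieber-style modified polyfit)
# ---------------------------------------------------------------------------

def _design_matrix(wavenumbers: np.ndarray, order: int) -> np.ndarray:
    # scale to [-1, 1] for conditioning
    x = (wavenumbers - wavenumbers[0]) / (wavenumbers[-1] - wavenumbers[0])
    x = 2.0 * x - 1.0
    return np.polynomial.polynomial.polyvander(x, order)


def iterative_baseline_matrix(Y: np.ndarray, wavenumbers: np.ndarray,
                              order: int, iterations: int,
                              tolerance: float) -> np.ndarray:
    """Vectorised iterative polynomial baseline for many spectra at once.

    ``Y`` has shape (n_spectra, channels).  Each iteration fits a
    degree-``order`` polynomial to the working copy by least squares and
    clips the working copy to ``min(working, fit + tolerance)``, so that
    peaks are progressively excluded while channels within the tolerance
    band (noise) keep contributing.  The fit of the final iteration is
    the baseline.
    """
    if order >= wavenumbers.size:
        raise ValueError(
            f"polynomial order {order} must be below the number of "
            f"channels ({wavenumbers.size})"
        )
    V = _design_matrix(wavenumbers, order)
    # unweighted LS: projection through the pseudo-inverse, shared by all rows
    pinv = np.linalg.pinv(V)
    work = np.asarray(Y, dtype=float).copy()
    fit = work
    for _ in range(iterations):
        coef = work @ pinv.T          # (n, order+1)
        fit = coef @ V.T              # (n, channels)
        work = np.minimum(work, fit + tolerance)
    return fit


def iterative_polynomial_baseline(
    spec: Spectrum, params: BaselineParams = BaselineParams()
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract a fluorescence baseline from one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = spec - baseline``.
    """
    base = iterative_baseline_matrix(
        spec.counts[None, :], spec.wavenumbers,
        params.order, params.iterations, params.tolerance,
    )[0]
    baseline = spec.with_counts(base)
    corrected = spec.with_counts(spec.counts - base)
    return baseline, corrected


# ---------------------------------------------------------------------------
# Band integration with a flat local baseline
# ---------------------------------------------------------------------------

def band_auc(
    spec: Spectrum,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    integration_window: tuple[float, float] = INTEGRATION_WINDOW,
) -> float:
    """Flat-baseline band area in counts * cm^-1 * s^-1.

    Subtracts the mean count level over ``baseline_window`` and integrates
    the remainder over ``integration_window`` by the trapezoid rule on the
    native grid (closed intervals), then normalises by the dwell time.
    """
    wn = spec.wavenumbers
    base_mask = window_mask(wn, baseline_window)
    int_mask = window_mask(wn, integration_window)
    flat = spec.counts[base_mask].mean()
    area = np.trapezoid(spec.counts[int_mask] - flat, wn[int_mask])
    return float(area / spec.dwell)


def band_auc_map(
    smap: SpectralMap,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    integration_window: tuple[float, float] = INTEGRATION_WINDOW,
    corrected: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel :func:`band_auc`; vectorised over the whole map.

    ``corrected`` optionally supplies a pre-baseline-corrected counts cube
    of the same shape as ``smap.counts``.
    """
    wn = smap.wavenumbers
    cube = smap.counts if corrected is None else corrected
    base_mask = window_mask(wn, baseline_window)
    int_mask = window_mask(wn, integration_window)
    flat = cube[..., base_mask].mean(axis=-1, keepdims=True)
    area = np.trapezoid(cube[..., int_mask] - flat, wn[int_mask], axis=-1)
    return area / smap.dwell


# ---------------------------------------------------------------------------
# Normalisation / centering
# ---------------------------------------------------------------------------

def normalize_fingerprint_auc(
    spec: Spectrum, region: tuple[float, float] = FINGERPRINT_REGION
) -> Spectrum:
    """Scale a spectrum so its AUC over the fingerprint region equals 1."""
    mask = window_mask(spec.wavenumbers, region)
    auc = np.trapezoid(spec.counts[mask], spec.wavenumbers[mask])
    if not auc > 0:
        raise ValueError(f"fingerprint AUC must be positive, got {auc}")
    return spec.with_counts(spec.counts / auc)


def normalize_rows_auc(X: np.ndarray, wavenumbers: np.ndarray,
                       region: tuple[float, float] = FINGERPRINT_REGION
                       ) -> np.ndarray:
    """Row-wise fingerprint-AUC normalisation of an (n, channels) matrix."""
    mask = window_mask(wavenumbers, region)
    auc = np.trapezoid(X[:, mask], wavenumbers[mask], axis=1)
    if np.any(auc <= 0):
        raise ValueError("all spectra must have positive fingerprint AUC")
    return X / auc[:, None]


def mean_center_scan(smap: SpectralMap, floor: float = 0.0) -> SpectralMap:
    """Scan mean-centering used before k-means clustering.

    Each pixel spectrum is divided channel-wise by the scan-average
    spectrum and multiplied by the scalar standard deviation of its own
    original counts, reducing the effect of illumination differences
    among scans while preserving per-pixel contrast.
    """
    avg = smap.flat().mean(axis=0) + floor
    if np.any(avg <= 0):
        raise ValueError(
            "scan-average spectrum must be strictly positive on all "
            "channels (consider a positive floor)"
        )
    sd = smap.counts.std(axis=-1, keepdims=True)
    centered = smap.counts / avg[None, None, :] * sd
    return SpectralMap(smap.wavenumbers, centered, step_um=smap.step_um,
                       dwell=smap.dwell,
                       meta=dict(smap.meta, mean_centered=True))


# ---------------------------------------------------------------------------
# Display-only smoothing and difference spectra
# ---------------------------------------------------------------------------

def savgol_smooth(spec: Spectrum, window: int = 11, order: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing.  Display only - never in quantification."""
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    return spec.with_counts(savgol_filter(spec.counts, window, order))


def mean_difference_spectrum(
    group_a: list[Spectrum],
    group_b: list[Spectrum],
    baseline_params: BaselineParams | None = None,
) -> Spectrum:
    """mean(A) - mean(B), optionally after per-spectrum baseline removal."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    axis = group_a[0].wavenumbers
    for s in list(group_a) + list(group_b):
        if s.wavenumbers.shape != axis.shape or not np.allclose(
                s.wavenumbers, axis):
            raise ValueError("all spectra must share one wavenumber axis")

    def _prep(s: Spectrum) -> np.ndarray:
        if baseline_params is None:
            return s.counts
        return iterative_polynomial_baseline(s, baseline_params)[1].counts

    mean_a = np.mean([_prep(s) for s in group_a], axis=0)
    mean_b = np.mean([_prep(s) for s in group_b], axis=0)
    return Spectrum(axis, mean_a - mean_b, dwell=group_a[0].dwell,
                    meta={"derived": "mean-difference"})
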