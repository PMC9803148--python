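"""Raman spectrum preprocessing.

Stages, in pipeline order: window cropping, shape-preserving (PCHIP)
interpolation onto a common axis, Savitzky-Golay smoothing, iterative
SG-based baseline estimation and subtraction, area (AUC) normalization, and
phenylalanine-band (~1005 cm^-1) alignment across a dataset.

The baseline estimator is the iterative peak-stripping scheme: start from
the spectrum itself, repeatedly smooth with a first-order SG filter whose
window is a fixed fraction of the channel count, and keep the pointwise
minimum of the current estimate and its smooth.  Peaks are progressively
shaved off while smooth background survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

logger = logging.getLogger("ramangrade.preprocess")

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "PreprocessConfig",
    "crop_window",
    "interpolate_to_axis",
    "sg_smooth",
    "estimate_baseline",
    "subtract_baseline",
    "auc_normalize",
    "fit_reference_peak",
    "align_dataset",
    "preprocess_pipeline",
]


def _check_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 1:
        raise ValueError("wavenumber axis must be a non-empty 1-D vector")
    if not np.isfinite(axis).all():
        raise ValueError("wavenumber axis contains non-finite values")
    if not (np.diff(axis) > 0).all():
        raise ValueError("wavenumber axis must be strictly increasing")
    return axis


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: intensities on a strictly increasing wavenumber axis."""

    axis: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _check_axis(self.axis))
        inten = np.asarray(self.intensities, dtype=float)
        if inten.shape != self.axis.shape:
            raise ValueError(
                f"intensities shape {inten.shape} does not match axis shape {self.axis.shape}")
        if not np.isfinite(inten).all():
            raise ValueError("intensities contain non-finite values")
        object.__setattr__(self, "intensities", inten)

    def with_values(self, intensities: np.ndarray, axis: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(self.axis if axis is None else axis, intensities)


@dataclass
class SpectralDataset:
    """n spectra x p channels on a shared axis, with per-spectrum metadata."""

    axis: np.ndarray
    matrix: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.axis.size:
            raise ValueError(
                f"matrix shape {self.matrix.shape} incompatible with axis length {self.axis.size}")
        if len(self.metadata) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.metadata)} metadata rows for {self.matrix.shape[0]} spectra")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.matrix[i])

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        mask = np.asarray(mask)
        return SpectralDataset(
            axis=self.axis,
            matrix=self.matrix[mask],
            metadata=self.metadata.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            .reset_index(drop=True),
        )


@dataclass
class PreprocessConfig:
    """Stage parameters; defaults follow the dispersive-Raman protocol."""

    sg_window: int = 3
    sg_order: int = 1
    baseline_window_frac: float = 0.07
    baseline_iterations: int = 20
    align_center: float = 1005.0
    align_halfwidth: float = 15.0
    align_passes: int = 2
    window_lo: float = 461.0
    window_hi: float = 1606.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < 1:
            raise ValueError("sg_window must be a positive odd integer")
        if not self.sg_order < self.sg_window:
            raise ValueError("sg_order must be < sg_window")
        if not 0 < self.baseline_window_frac < 1:
            raise ValueError("baseline_window_frac must be in (0, 1)")
        if self.baseline_iterations < 1:
            raise ValueError("baseline_iterations must be >= 1")
        if not self.window_lo < self.window_hi:
            raise ValueError("window_lo must be < window_hi")


# ---------------------------------------------------------------------------
# single-spectrum operations (array cores + Spectrum wrappers)
# ---------------------------------------------------------------------------

def crop_window(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep channels with lo <= wavenumber <= hi (both ends inclusive)."""
    if not lo <= hi:
        raise ValueError(f"inverted crop window [{lo}, {hi}]")
    mask = (s.axis >= lo) & (s.axis <= hi)
    if not mask.any():
        raise ValueError(f"crop window [{lo}, {hi}] contains no channels")
    return Spectrum(s.axis[mask], s.intensities[mask])


def interpolate_to_axis(s: Spectrum, target: np.ndarray) -> Spectrum:
    """Monotone (shape-preserving) piecewise-cubic resampling onto *target*.

    PCHIP interpolation never overshoots beyond neighbouring knot values, so
    resampled intensities stay within each local data interval.  No
    extrapolation: the target axis must lie inside the source range.
    """
    target = _check_axis(target)
    if target[0] < s.axis[0] - 1e-12 or target[-1] > s.axis[-1] + 1e-12:
        raise ValueError(
            f"target axis [{target[0]}, {target[-1]}] outside source range "
            f"[{s.axis[0]}, {s.axis[-1]}]")
    vals = PchipInterpolator(s.axis, s.intensities)(np.clip(target, s.axis[0], s.axis[-1]))
    return Spectrum(target, vals)


def _sg(values: np.ndarray, window: int, order: int) -> np.ndarray:
    # mirror padding avoids endpoint collapse on short windows
    return savgol_filter(values, window_length=window, polyorder=order, axis=-1, mode="mirror")


def sg_smooth(s: Spectrum, window: int = 3, order: int = 1) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing."""
    if window % 2 == 0 or window < 1:
        raise ValueError("SG window must be a positive odd integer")
    if not order < window:
        raise ValueError("SG order must be < window")
    if window > s.intensities.size:
        raise ValueError(f"SG window {window} exceeds spectrum length {s.intensities.size}")
    return s.with_values(_sg(s.intensities, window, order))


def _baseline_window(n_channels: int, window_frac: float) -> int:
    window = int(round(window_frac * n_channels))
    if window % 2 == 0:
        window += 1
    if window < 3:
        logger.warning("baseline SG window %d below minimum; clamped to 3", window)
        window = 3
    return min(window, n_channels if n_channels % 2 == 1 else n_channels - 1)


def _estimate_baseline_matrix(matrix: np.ndarray, window_frac: float, iterations: int) -> np.ndarray:
    window = _baseline_window(matrix.shape[-1], window_frac)
    b = matrix.astype(float, copy=True)
    for _ in range(iterations):
        b = np.minimum(b, _sg(b, window, 1))
    return b


def estimate_baseline(s: Spectrum, window_frac: float = 0.07, iterations: int = 20) -> Spectrum:
    """Iterative peak-stripping baseline estimate.

    b_0 = s; each round, b_{k+1} = min(b_k, SG(b_k)) with a first-order SG
    filter whose window is ``round(window_frac * n_channels)`` forced odd.
    The estimate is pointwise non-increasing over iterations.
    """
    if not 0 < window_frac < 1:
        raise ValueError("window_frac must be in (0, 1)")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    return s.with_values(_estimate_baseline_matrix(s.intensities, window_frac, iterations))


def subtract_baseline(s: Spectrum, b: Spectrum) -> Spectrum:
    """s - b with negative residuals clamped to 0 (downstream NMF needs X >= 0)."""
    if s.axis.shape != b.axis.shape or not np.allclose(s.axis, b.axis):
        raise ValueError("spectrum and baseline are on different axes")
    return s.with_values(np.maximum(s.intensities - b.intensities, 0.0))


def auc_normalize(s: Spectrum) -> Spectrum:
    """Scale so the trapezoidal area under the spectrum equals 1."""
    area = np.trapezoid(s.intensities, s.axis)
    if area <= 0:
        raise ValueError(f"cannot AUC-normalize spectrum with area {area}")
    return s.with_values(s.intensities / area)


def _gauss_model(x, a, h, mu, sigma):
    return a + h * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_reference_peak(s: Spectrum, center: float = 1005.0, halfwidth: float = 15.0) -> float:
    """Fitted center of a Gaussian + offset restricted to center +/- halfwidth.

    Falls back to the windowed argmax channel position when the data are
    degenerate (flat window) or the fit does not converge.
    """
    mask = (s.axis >= center - halfwidth) & (s.axis <= center + halfwidth)
    if mask.sum() < 5:
        raise ValueError(
            f"window {center}+/-{halfwidth} cm^-1 holds {int(mask.sum())} channels; need >= 5")
    x, y = s.axis[mask], s.intensities[mask]
    mu0 = float(x[np.argmax(y)])
    # re-centre the window on the detected peak so neighbouring bands bias
    # every spectrum's fit identically (the bias then cancels in shifts)
    mask = (s.axis >= mu0 - halfwidth) & (s.axis <= mu0 + halfwidth)
    x, y = s.axis[mask], s.intensities[mask]
    span = float(y.max() - y.min())
    if span <= 0:
        logger.warning("flat reference window at %g cm^-1; falling back to argmax", center)
        return mu0
    p0 = (float(y.min()), span, mu0, halfwidth / 3.0)
    try:
        popt, _ = curve_fit(_gauss_model, x, y, p0=p0, maxfev=2000)
    except (RuntimeError, ValueError):
        logger.warning("reference-peak fit failed near %g cm^-1; falling back to argmax", center)
        return mu0
    mu = float(popt[2])
    if not (x[0] <= mu <= x[-1]):
        logger.warning("reference-peak fit left the window near %g cm^-1; using argmax", center)
        return mu0
    return mu


def _shift_spectrum(axis: np.ndarray, values: np.ndarray, delta: float) -> np.ndarray:
    """Shift a spectrum by *delta* cm^-1 along the axis (edge-value fill)."""
    if delta == 0.0:
        return values.copy()
    query = np.clip(axis - delta, axis[0], axis[-1])
    return PchipInterpolator(axis, values)(query)


# ---------------------------------------------------------------------------
# dataset-level operations
# ---------------------------------------------------------------------------

def align_dataset(d: SpectralDataset, cfg: PreprocessConfig | None = None) -> SpectralDataset:
    """Align every spectrum's reference band to the first spectrum's.

    The Gaussian-fitted phenylalanine center of the first spectrum defines
    the target; every spectrum is shifted by (target - own center) through
    the shape-preserving interpolant, and the whole pass is repeated
    ``align_passes`` times.  Cumulative shifts are recorded in the metadata
    column ``alignment_shift``.
    """
    cfg = cfg or PreprocessConfig()
    if d.n_spectra == 0:
        raise ValueError("cannot align an empty dataset")
    matrix = d.matrix.copy()
    total_shift = np.zeros(d.n_spectra)
    for _ in range(cfg.align_passes):
        mu_ref = fit_reference_peak(Spectrum(d.axis, matrix[0]), cfg.align_center, cfg.align_halfwidth)
        for i in range(d.n_spectra):
            mu_i = fit_reference_peak(Spectrum(d.axis, matrix[i]), cfg.align_center, cfg.align_halfwidth)
            delta = mu_ref - mu_i
            if delta != 0.0:
                matrix[i] = _shift_spectrum(d.axis, matrix[i], delta)
                total_shift[i] += delta
    metadata = d.metadata.copy()
    metadata["alignment_shift"] = total_shift
    return SpectralDataset(axis=d.axis, matrix=matrix, metadata=metadata)


def preprocess_pipeline(d: SpectralDataset, cfg: PreprocessConfig | None = None) -> SpectralDataset:
    """crop -> SG smooth -> baseline estimate/subtract -> AUC normalize -> align.

    Output spectra are non-negative and unit-area before alignment;
    alignment perturbs the area by < 1% in practice.
    """
    cfg = cfg or PreprocessConfig()
    if d.n_spectra == 0:
        raise ValueError("cannot preprocess an empty dataset")
    mask = (d.axis >= cfg.window_lo) & (d.axis <= cfg.window_hi)
    if not mask.any():
        raise ValueError(
            f"crop window [{cfg.window_lo}, {cfg.window_hi}] contains no channels")
    axis = d.axis[mask]
    matrix = d.matrix[:, mask]
    logger.info("crop: kept %d of %d channels", axis.size, d.axis.size)

    matrix = _sg(matrix, cfg.sg_window, cfg.sg_order)
    baseline = _estimate_baseline_matrix(matrix, cfg.baseline_window_frac, cfg.baseline_iterations)
    matrix = np.maximum(matrix - baseline, 0.0)

    areas = np.trapezoid(matrix, axis, axis=-1)
    if (areas <= 0).any():
        bad = int((areas <= 0).sum())
        raise ValueError(f"{bad} spectra have non-positive area after baseline subtraction")
    matrix = matrix / areas[:, None]
    logger.info("preprocessed %d spectra: smoothed, baseline-subtracted, unit-area", matrix.shape[0])

    aligned = align_dataset(SpectralDataset(axis=axis, matrix=matrix, metadata=d.metadata.copy()), cfg)
    # the shape-preserving shift cannot overshoot, but float rounding can
    # leave values at -1e-20; clamp so downstream NMF sees X >= 0 exactly
    aligned.matrix = np.maximum(aligned.matrix, 0.0)
    return aligned
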