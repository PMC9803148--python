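"""Synthetic Raman spectral-map generator.

Emulates dispersive Raman maps of cryopreserved murine lung sections: each
region of interest (ROI) contributes 30-80 point spectra, every point being a
non-negative mixture of a lung-tissue signature, an OCT:PBS mounting-media
signature, and their 50/50 "contaminated" average, sitting on a smooth
fluorescence-like baseline with additive detector noise and a small
wavenumber-calibration jitter.  Fibrotic burden enters as collagen bands
whose amplitude scales linearly with the region's grade, which is what the
downstream classifier is asked to recover.

All latent quantities (mixing weights, baselines, grades, axis shifts) are
returned as a :class:`GroundTruth` so that every downstream stage can be
tested against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import SpectralDataset
from .unmixing import BasisSet

__all__ = [
    "PeakSpec",
    "SyntheticConfig",
    "GroundTruth",
    "make_axis",
    "make_basis_library",
    "simulate_dataset",
    "FIBROSIS_GRADES",
    "PNEUMONITIS_GRADES",
    "DEFAULT_TISSUE_PEAKS",
    "DEFAULT_MEDIA_PEAKS",
    "DEFAULT_COLLAGEN_PEAKS",
]

#: Fibrosis grades (fraction of region assessed fibrotic on Trichrome).
FIBROSIS_GRADES: tuple[float, ...] = (0.0, 0.05, 0.1, 0.3, 0.5, 0.6, 0.9, 1.0)

#: Pneumonitis grades (region-level inflammation score, rescaled to [0, 1]).
PNEUMONITIS_GRADES: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 0.8)


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian Raman band: center (cm^-1), sigma (cm^-1), amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.center, self.width, self.amplitude]).all():
            raise ValueError("PeakSpec fields must be finite")
        if self.width <= 0:
            raise ValueError(f"peak width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"peak amplitude must be >= 0, got {self.amplitude}")


# Band positions follow common assignments for protein-rich soft tissue
# (Phe ring breathing at 1005, CH2 deformation at 1448, amide III near 1265,
# amide I shoulder at 1585 within this window) and a PEG/polyol-like mounting
# medium.  Amplitudes are relative; the Phe band is the most prominent, as it
# is the alignment reference.
DEFAULT_TISSUE_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(621.0, 7.0, 0.45),
    PeakSpec(757.0, 7.0, 0.55),
    PeakSpec(852.0, 8.0, 0.65),
    PeakSpec(936.0, 8.0, 0.50),
    PeakSpec(1005.0, 4.0, 1.60),
    PeakSpec(1031.0, 7.0, 0.70),
    PeakSpec(1080.0, 9.0, 0.75),
    PeakSpec(1126.0, 8.0, 0.55),
    PeakSpec(1265.0, 11.0, 0.70),
    PeakSpec(1448.0, 11.0, 1.00),
    PeakSpec(1585.0, 9.0, 0.50),
)

DEFAULT_MEDIA_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(528.0, 10.0, 0.60),
    PeakSpec(845.0, 9.0, 1.00),
    PeakSpec(1065.0, 10.0, 0.90),
    PeakSpec(1140.0, 9.0, 0.80),
    PeakSpec(1235.0, 10.0, 0.60),
)

# Collagen markers: proline ring (855), hydroxyproline/C-C backbone (938) and
# the collagen amide III band (1245).  Amplitudes are on the same relative
# scale as the tissue bands; the region grade multiplies this component.
DEFAULT_COLLAGEN_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(855.0, 8.0, 0.90),
    PeakSpec(938.0, 8.0, 0.80),
    PeakSpec(1245.0, 12.0, 1.00),
)


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated acquisition campaign.

    Defaults mirror the acquisition geometry of the murine lung study this
    pipeline targets: a 678-channel window over [461, 1606] cm^-1, maps of
    30-80 points, the eight-level fibrosis grade set, and an air-pocket
    contamination rate chosen so that roughly 60% of spectra survive the
    media filter.
    """

    n_channels: int = 678
    axis_lo: float = 461.0
    axis_hi: float = 1606.0
    tissue_peaks: Sequence[PeakSpec] = DEFAULT_TISSUE_PEAKS
    media_peaks: Sequence[PeakSpec] = DEFAULT_MEDIA_PEAKS
    collagen_peaks: Sequence[PeakSpec] = DEFAULT_COLLAGEN_PEAKS
    grade_levels: Sequence[float] = FIBROSIS_GRADES
    n_maps_per_grade: int = 3
    points_per_map: tuple[int, int] = (30, 80)
    media_mix_fraction_range: tuple[float, float] = (0.0, 0.2)
    air_pocket_rate: float = 0.4
    baseline_kind: str = "polynomial"
    baseline_scale: float = 5e-3
    noise_sd: float = 2e-4
    shift_jitter_sd: float = 0.3
    seed: int = 0
    #: Which pathology column the simulated grades populate.
    response: str = "fibrosis"
    #: Optional per-strain grade subsets, e.g. C3H/HeJ fibrosis only shows
    #: grades {0, 0.1, 0.3, 0.5}.  None = one strain with ``grade_levels``.
    strain_grades: Mapping[str, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 8:
            raise ValueError("n_channels must be >= 8")
        if not self.axis_lo < self.axis_hi:
            raise ValueError("axis_lo must be < axis_hi")
        if not 0 <= self.air_pocket_rate <= 1:
            raise ValueError("air_pocket_rate must be in [0, 1]")
        lo, hi = self.media_mix_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("media_mix_fraction_range must be within [0, 1]")
        plo, phi = self.points_per_map
        if plo < 1 or phi < plo:
            raise ValueError("points_per_map must be a positive (lo, hi) range")
        if self.baseline_kind not in ("polynomial", "exponential"):
            raise ValueError(f"unknown baseline_kind {self.baseline_kind!r}")
        if self.response not in ("fibrosis", "pneumonitis"):
            raise ValueError(f"response must be fibrosis|pneumonitis, got {self.response!r}")
        for g in self.grade_levels:
            if not 0 <= g <= 1:
                raise ValueError(f"grade level {g} outside [0, 1]")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated dataset."""

    weights: np.ndarray        # (n, 3) true non-negative mixing weights
    basis_labels: tuple[str, str, str]
    baselines: np.ndarray      # (n, p) additive baseline per spectrum
    grades: np.ndarray         # (n,) true region grade
    shifts: np.ndarray         # (n,) applied axis shift, cm^-1
    collagen_component: np.ndarray  # (p,) unit collagen signature on the axis

    def __post_init__(self) -> None:
        n = self.weights.shape[0]
        if not (self.baselines.shape[0] == self.grades.shape[0] == self.shifts.shape[0] == n):
            raise ValueError("GroundTruth arrays must share the spectrum dimension")
        if (self.weights < 0).any():
            raise ValueError("true mixing weights must be non-negative")


def make_axis(n_channels: int, lo: float, hi: float) -> np.ndarray:
    """Equally spaced wavenumber axis from *lo* to *hi* inclusive."""
    if n_channels < 2:
        raise ValueError("axis needs at least 2 channels")
    if not lo < hi:
        raise ValueError(f"inverted axis range [{lo}, {hi}]")
    return np.linspace(lo, hi, n_channels)


def _gaussian_sum(axis: np.ndarray, peaks: Sequence[PeakSpec]) -> np.ndarray:
    out = np.zeros_like(axis, dtype=float)
    for pk in peaks:
        out += pk.amplitude * np.exp(-((axis - pk.center) ** 2) / (2.0 * pk.width**2))
    return out


def _check_peaks_on_axis(peaks: Sequence[PeakSpec], lo: float, hi: float, name: str) -> None:
    if not peaks:
        raise ValueError(f"{name} peak list must be non-empty")
    for pk in peaks:
        if not lo <= pk.center <= hi:
            raise ValueError(f"{name} peak center {pk.center} outside axis [{lo}, {hi}]")


def make_basis_library(config: SyntheticConfig) -> BasisSet:
    """Build the three fixed unmixing bases on the configured axis.

    tissue = the tissue band sum, media = the media band sum, and mixed =
    their 50/50 average (a stand-in for spectra contaminated by residual
    media in air pockets).  Each basis is normalized to unit trapezoidal
    area.  Note the mixed basis is, by this convention, exactly in the span
    of the other two.
    """
    axis = make_axis(config.n_channels, config.axis_lo, config.axis_hi)
    _check_peaks_on_axis(config.tissue_peaks, config.axis_lo, config.axis_hi, "tissue")
    _check_peaks_on_axis(config.media_peaks, config.axis_lo, config.axis_hi, "media")
    if not any(abs(pk.center - 1005.0) <= 10.0 for pk in config.tissue_peaks):
        raise ValueError("tissue peaks must include a band near 1005 cm^-1 (alignment reference)")
    tissue = _gaussian_sum(axis, config.tissue_peaks)
    media = _gaussian_sum(axis, config.media_peaks)
    tissue = tissue / np.trapezoid(tissue, axis)
    media = media / np.trapezoid(media, axis)
    mixed = 0.5 * (tissue + media)
    mixed = mixed / np.trapezoid(mixed, axis)
    return BasisSet(labels=("tissue", "mixed", "media"), spectra=np.vstack([tissue, mixed, media]), axis=axis)


def _draw_baseline(axis: np.ndarray, kind: str, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive baseline: low-order polynomial or decaying exponential."""
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    if kind == "polynomial":
        c0 = rng.uniform(0.5, 1.0)
        cs = rng.uniform(-0.15, 0.15, size=3)
        # c0 dominates the odd terms, keeping the baseline strictly positive
        b = c0 + cs[0] * u + cs[1] * u**2 + cs[2] * u**3
    else:  # exponential
        k = rng.uniform(1.0, 3.0)
        b = rng.uniform(0.5, 1.0) * np.exp(-k * u)
    return scale * b


def simulate_dataset(config: SyntheticConfig) -> tuple[SpectralDataset, GroundTruth]:
    """Draw a full spectral-map campaign under *config*.

    For every (strain, grade, map) cell, a uniformly drawn number of point
    spectra is generated.  A point is either ordinary tissue (media fraction
    drawn from ``media_mix_fraction_range``) or, with probability
    ``air_pocket_rate``, an air pocket dominated by the media signature.
    Each point spectrum is

        s = w_t * tissue_g + w_x * mixed + w_m * media + baseline + noise

    where tissue_g = tissue + grade * collagen and all component signatures
    are evaluated on the jittered axis (calibration drift).  Identical seeds
    give identical output.
    """
    if len(config.grade_levels) == 0:
        raise ValueError("grade_levels must be non-empty")
    rng = np.random.default_rng(config.seed)
    axis = make_axis(config.n_channels, config.axis_lo, config.axis_hi)
    if config.collagen_peaks:
        _check_peaks_on_axis(config.collagen_peaks, config.axis_lo, config.axis_hi, "collagen")

    # Shared normalization constants so the shifted per-spectrum signatures
    # stay on the same scale as the basis library.
    raw_t = _gaussian_sum(axis, config.tissue_peaks)
    raw_m = _gaussian_sum(axis, config.media_peaks)
    area_t = np.trapezoid(raw_t, axis)
    area_m = np.trapezoid(raw_m, axis)
    raw_x = 0.5 * (raw_t / area_t + raw_m / area_m)
    area_x = np.trapezoid(raw_x, axis)

    def components(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = _gaussian_sum(x, config.tissue_peaks) / area_t
        m = _gaussian_sum(x, config.media_peaks) / area_m
        mixed = (0.5 * (_gaussian_sum(x, config.tissue_peaks) / area_t
                        + _gaussian_sum(x, config.media_peaks) / area_m)) / area_x
        c = (_gaussian_sum(x, config.collagen_peaks) / area_t
             if config.collagen_peaks else np.zeros_like(x))
        return t, mixed, m, c

    strain_plan: dict[str, Sequence[float]]
    if config.strain_grades is None:
        strain_plan = {"C57BL/6J": tuple(config.grade_levels)}
    else:
        strain_plan = {k: tuple(v) for k, v in config.strain_grades.items()}

    rows, meta_rows, w_rows, base_rows, grade_rows, shift_rows = [], [], [], [], [], []
    mouse_counter = 0
    for strain, grades in strain_plan.items():
        for grade in grades:
            for imap in range(config.n_maps_per_grade):
                mouse_counter += 1
                mouse_id = f"m{mouse_counter:03d}"
                map_id = f"{mouse_id}_roi{imap + 1}"
                npts = int(rng.integers(config.points_per_map[0], config.points_per_map[1] + 1))
                for ipt in range(npts):
                    is_air = rng.uniform() < config.air_pocket_rate
                    if is_air:
                        beta = rng.uniform(0.55, 0.9)          # media proportion
                        gamma = rng.uniform(0.0, 0.5) * (1 - beta)
                        props = np.array([1 - beta - gamma, gamma, beta])
                    else:
                        alpha = rng.uniform(*config.media_mix_fraction_range)
                        gamma = rng.uniform(0.0, 0.1)
                        props = np.array([1 - alpha - gamma, gamma, alpha])
                    scale = rng.uniform(0.9, 1.1)
                    w = scale * props
                    delta = rng.normal(0.0, config.shift_jitter_sd) if config.shift_jitter_sd > 0 else 0.0
                    t, x_, m, c = components(axis - delta)
                    signal = w[0] * (t + grade * c) + w[1] * x_ + w[2] * m
                    baseline = (_draw_baseline(axis, config.baseline_kind, config.baseline_scale, rng)
                                if config.baseline_scale > 0 else np.zeros_like(axis))
                    noise = (rng.normal(0.0, config.noise_sd, size=axis.size)
                             if config.noise_sd > 0 else 0.0)
                    rows.append(signal + baseline + noise)
                    w_rows.append(w)
                    base_rows.append(baseline)
                    grade_rows.append(grade)
                    shift_rows.append(delta)
                    fib = grade if config.response == "fibrosis" else 0.0
                    pneu = grade if config.response == "pneumonitis" else 0.0
                    meta_rows.append({
                        "spectrum_id": f"{map_id}_p{ipt + 1:03d}",
                        "mouse_id": mouse_id,
                        "strain": strain,
                        "map_id": map_id,
                        "fibrosis_grade": fib,
                        "pneumonitis_grade": pneu,
                    })

    matrix = np.asarray(rows)
    metadata = pd.DataFrame(meta_rows)
    dataset = SpectralDataset(axis=axis, matrix=matrix, metadata=metadata)
    _, _, _, collagen_unit = components(axis)
    truth = GroundTruth(
        weights=np.asarray(w_rows),
        basis_labels=("tissue", "mixed", "media"),
        baselines=np.asarray(base_rows),
        grades=np.asarray(grade_rows),
        shifts=np.asarray(shift_rows),
        collagen_component=collagen_unit,
    )
    return dataset, truth
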