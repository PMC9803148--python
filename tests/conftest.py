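import numpy as np
import pandas as pd
import pytest

from ramangrade import (BasisSet, SpectralDataset, SyntheticConfig, make_axis,
                        simulate_dataset)
from ramangrade.synthetic import PeakSpec


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Small but structurally faithful campaign: full axis, 3 grades."""
    return SyntheticConfig(
        grade_levels=(0.0, 0.5, 1.0),
        n_maps_per_grade=1,
        points_per_map=(12, 20),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def independent_basis() -> BasisSet:
    """Three linearly independent, disjoint-band basis spectra.

    The default library's mixed basis is by convention the average of the
    other two (rank 2), which leaves per-spectrum weights unidentifiable;
    weight-recovery checks need an independent library.
    """
    axis = make_axis(300, 461.0, 1606.0)

    def bands(peaks):
        s = np.zeros_like(axis)
        for c, w, a in peaks:
            s += a * np.exp(-((axis - c) ** 2) / (2 * w**2))
        return s / np.trapezoid(s, axis)

    spectra = np.vstack([
        bands([(600, 10, 1.0), (1005, 8, 1.5), (1400, 12, 0.8)]),
        bands([(750, 10, 1.0), (1100, 9, 1.2)]),
        bands([(900, 10, 0.9), (1250, 10, 1.1), (1550, 9, 0.7)]),
    ])
    return BasisSet(labels=("tissue", "mixed", "media"), spectra=spectra, axis=axis)


def make_toy_dataset(n_per_class=30, classes=(0.0, 0.5, 1.0), p=30, sep=1.0, seed=0,
                     strain="C57BL/6J"):
    """Tiny labelled dataset for classifier tests: each class shifts a few
    channels by `sep` units of noise."""
    rng = np.random.default_rng(seed)
    axis = np.linspace(461, 1606, p)
    rows, grades = [], []
    for k, g in enumerate(classes):
        X = rng.normal(0, 1, (n_per_class, p))
        X[:, 3 * k:3 * k + 3] += sep * (k + 1)
        rows.append(X)
        grades.extend([g] * n_per_class)
    matrix = np.vstack(rows) - np.vstack(rows).min() + 0.01  # keep non-negative
    n = matrix.shape[0]
    meta = pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(n)],
        "mouse_id": "m1",
        "strain": strain,
        "map_id": "m1_roi1",
        "fibrosis_grade": grades,
        "pneumonitis_grade": 0.0,
    })
    return SpectralDataset(axis=axis, matrix=matrix, metadata=meta)
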