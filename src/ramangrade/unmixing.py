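"""Group- and basis-restricted NMF (GBR-NMF) and air-pocket filtering.

Each preprocessed spectrum is decomposed against a small library of fixed,
known basis spectra (lung tissue, media-contaminated "mixed" tissue, and
OCT:PBS mounting media): X ~ W H with the rows of H pinned to the library
and W >= 0.  With every basis fixed, the factorization separates row-wise
into independent non-negative least-squares problems, which are solved
exactly — deterministic, optimal, and free of initialization effects.  An
alternating solver handles the optional case of additional free
(unconstrained, learned) basis rows.

Scores are column-normalized to unit mean so that the filtering thresholds
("tissue score >= 1, media score <= 1") are expressed relative to the mean
score of each basis, and spectra dominated by media — air pockets holding
residual OCT:PBS — are removed exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

logger = logging.getLogger("ramangrade.unmixing")

__all__ = [
    "BasisSet",
    "ScoreMatrix",
    "FilterResult",
    "fit_gbr_nmf",
    "normalize_scores",
    "filter_spectra",
]


@dataclass
class BasisSet:
    """Ordered fixed basis spectra (rows of H) on the dataset axis."""

    labels: tuple[str, ...]
    spectra: np.ndarray  # (q, p), non-negative
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[0] != len(self.labels):
            raise ValueError("basis matrix must be (q, p) with one row per label")
        if self.spectra.shape[1] != self.axis.size:
            raise ValueError("basis spectra and axis disagree on channel count")
        if (self.spectra < 0).any():
            raise ValueError("basis spectra must be non-negative")
        areas = np.trapezoid(self.spectra, self.axis, axis=-1)
        if (areas <= 0).any():
            raise ValueError("every basis spectrum must have positive area")

    @property
    def q(self) -> int:
        return self.spectra.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label) if isinstance(self.labels, list) else tuple(self.labels).index(label)
        except ValueError as exc:
            raise KeyError(f"basis label {label!r} not in {self.labels}") from exc


@dataclass
class ScoreMatrix:
    """Fitted weights W of X ~ WH, plus the column-mean-normalized form."""

    labels: tuple[str, ...]
    raw: np.ndarray                    # (n, q) >= 0
    residuals: np.ndarray              # (n,) per-spectrum residual norms
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if (self.raw < -1e-12).any():
            raise ValueError("raw scores must be non-negative")
        if self.raw.shape[1] != len(self.labels):
            raise ValueError("one score column per basis label required")

    def column(self, label: str, normalized: bool = True) -> np.ndarray:
        idx = tuple(self.labels).index(label)
        if normalized:
            if self.normalized is None:
                raise ValueError("scores have not been normalized; call normalize_scores first")
            return self.normalized[:, idx]
        return self.raw[:, idx]


@dataclass
class FilterResult:
    """Keep/discard decision per spectrum from the score thresholds."""

    keep_mask: np.ndarray
    retention: float
    tissue_min: float
    media_max: float

    def __post_init__(self) -> None:
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if abs(self.retention - float(self.keep_mask.mean())) > 1e-12:
            raise ValueError("retention must equal mean(keep_mask)")


def _validate_X(X: np.ndarray, p: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != p:
        raise ValueError(f"data matrix shape {X.shape} incompatible with {p} basis channels")
    if (X < 0).any():
        raise ValueError("data matrix must be non-negative (clamp residuals upstream)")
    return X


def fit_gbr_nmf(
    X: np.ndarray,
    basis: BasisSet,
    free_rank: int = 0,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
) -> ScoreMatrix:
    """Fit non-negative weights of every spectrum against the fixed bases.

    With ``free_rank == 0`` each weight row solves min ||x_i - w H||, w >= 0
    exactly (active-set NNLS).  With ``free_rank > 0``, that many additional
    basis rows are learned by alternating NNLS updates; the fixed rows are
    never updated.  Returns raw scores for the fixed bases (free-basis
    weights are appended with labels ``free_1..free_r``).
    """
    if free_rank < 0:
        raise ValueError("free_rank must be >= 0")
    X = _validate_X(X, basis.spectra.shape[1])
    if (basis.spectra.sum(axis=1) == 0).any():
        raise ValueError("all-zero basis row")
    H = basis.spectra
    labels = tuple(basis.labels)

    if free_rank > 0:
        rng = np.random.default_rng(seed)
        scale = X.mean() if X.size else 1.0
        H_free = np.abs(rng.normal(scale, scale, size=(free_rank, H.shape[1])))
        labels = labels + tuple(f"free_{r + 1}" for r in range(free_rank))
        prev = np.inf
        for _ in range(max_iter):
            H_all = np.vstack([H, H_free])
            W = _solve_rows(X, H_all)
            # update only the free rows, channel by channel
            R = X - W[:, : basis.q] @ H
            Wf = W[:, basis.q:]
            for j in range(H.shape[1]):
                H_free[:, j], _ = nnls(Wf, R[:, j])
            err = float(np.linalg.norm(X - W @ np.vstack([H, H_free])))
            if abs(prev - err) <= tol * max(1.0, prev):
                break
            prev = err
        H_all = np.vstack([H, H_free])
        W = _solve_rows(X, H_all)
        resid = np.linalg.norm(X - W @ H_all, axis=1)
    else:
        W = _solve_rows(X, H)
        resid = np.linalg.norm(X - W @ H, axis=1)

    logger.info("GBR-NMF: fitted %d spectra against %d bases (free_rank=%d), "
                "median residual %.3g", X.shape[0], len(labels), free_rank, float(np.median(resid)))
    return ScoreMatrix(labels=labels, raw=W, residuals=resid)


def _solve_rows(X: np.ndarray, H: np.ndarray) -> np.ndarray:
    A = H.T  # (p, q)
    W = np.empty((X.shape[0], H.shape[0]))
    for i in range(X.shape[0]):
        W[i], _ = nnls(A, X[i])
    return W


def normalize_scores(scores: ScoreMatrix) -> ScoreMatrix:
    """Scale each score column to unit mean (threshold 1 == the column mean).

    Columns whose mean is zero are left at zero and flagged in the log.
    """
    means = scores.raw.mean(axis=0)
    normalized = np.zeros_like(scores.raw)
    for j, m in enumerate(means):
        if m > 0:
            normalized[:, j] = scores.raw[:, j] / m
        else:
            logger.warning("score column %r has zero mean; left at zero", scores.labels[j])
    return ScoreMatrix(labels=scores.labels, raw=scores.raw,
                       residuals=scores.residuals, normalized=normalized)


def filter_spectra(
    scores: ScoreMatrix,
    tissue_min: float = 1.0,
    media_max: float = 1.0,
    *,
    tissue_label: str = "tissue",
    media_label: str = "media",
) -> FilterResult:
    """Keep spectra with tissue score >= tissue_min AND media score <= media_max.

    Thresholds apply to the column-mean-normalized scores; both comparisons
    are inclusive.  The mixed-basis score is not thresholded.
    """
    if tissue_min < 0 or media_max < 0:
        raise ValueError("score thresholds must be non-negative")
    tissue = scores.column(tissue_label, normalized=True)
    media = scores.column(media_label, normalized=True)
    keep = (tissue >= tissue_min) & (media <= media_max)
    retention = float(keep.mean())
    logger.info("filter: kept %d of %d spectra (retention %.1f%%)",
                int(keep.sum()), keep.size, 100.0 * retention)
    return FilterResult(keep_mask=keep, retention=retention,
                        tissue_min=tissue_min, media_max=media_max)
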