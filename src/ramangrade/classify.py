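"""Multinomial LASSO grading of lung-toxicity spectra.

The pathology grade of a region is a fraction in [0, 1] (percent of the
region diseased), so the grades are treated as nominal classes and fitted
with an L1-penalized multinomial (softmax) logistic model

    min_{B, b}  (1/n) sum_i -log softmax(x_i B + b)_{y_i}  +  lam * ||B||_1

in the symmetric parameterization (no reference class; the penalty resolves
the shift ambiguity of the coefficient block).  The solver is a monotone
accelerated proximal-gradient method (MFISTA): soft-thresholding yields
exact zeros, warm starts make the 100-point penalty path cheap, and for
lam >= lam_max the exact null model (zero coefficients, log-frequency
intercepts) is returned in closed form since it satisfies the KKT
conditions there.

The penalty is selected by stratified 10-fold cross-validation with the
one-standard-error rule on held-out multinomial deviance, and models are
evaluated with confusion matrices and the classification rate
CR = (1/n) sum_i 1(pred_i == true_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .preprocess import SpectralDataset

logger = logging.getLogger("ramangrade.classify")

__all__ = [
    "BinningScheme",
    "SCHEME_LMH",
    "SCHEME_ZLMH",
    "GradingModel",
    "CVResult",
    "ConfusionMatrix",
    "GradingReport",
    "ConvergenceError",
    "bin_grades",
    "split_train_test",
    "lambda_max",
    "lambda_grid",
    "fit_multinomial_lasso",
    "multinomial_deviance",
    "cv_select_lambda",
    "predict_proba",
    "predict_classes",
    "confusion_matrix",
    "classification_rate",
    "coefficient_map",
    "run_grading_experiment",
]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# grade binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningScheme:
    """Ordered, disjoint inclusive grade intervals, each with a label."""

    name: str
    bins: tuple[tuple[str, float, float], ...]  # (label, lo, hi) inclusive

    def __post_init__(self) -> None:
        for label, lo, hi in self.bins:
            if lo > hi:
                raise ValueError(f"bin {label!r} has inverted interval [{lo}, {hi}]")
        los = [b[1] for b in self.bins]
        his = [b[2] for b in self.bins]
        for i in range(1, len(self.bins)):
            if los[i] <= his[i - 1]:
                raise ValueError(f"bins of scheme {self.name!r} overlap or are unordered")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bins)

    def assign(self, grade: float) -> str:
        for label, lo, hi in self.bins:
            if lo - 1e-12 <= grade <= hi + 1e-12:
                return label
        raise ValueError(f"grade {grade} not covered by binning scheme {self.name!r}")


#: Three-level fibrosis binning: Low (0-0.1), Medium (0.3-0.6), High (0.9-1).
SCHEME_LMH = BinningScheme("lmh", (("Low", 0.0, 0.1), ("Medium", 0.3, 0.6), ("High", 0.9, 1.0)))

#: Four-level fibrosis binning: Zero (0), Low (0.05-0.3), Medium (0.5-0.6),
#: High (0.9-1).  The Low bin starts at 0.05 so every fibrosis grade is covered.
SCHEME_ZLMH = BinningScheme(
    "zlmh", (("Zero", 0.0, 0.0), ("Low", 0.05, 0.3), ("Medium", 0.5, 0.6), ("High", 0.9, 1.0)))


def bin_grades(grades: Sequence[float], scheme: BinningScheme) -> list[str]:
    """Map every grade to its bin label; errors name any uncovered grade."""
    return [scheme.assign(float(g)) for g in grades]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_train_test(
    d: SpectralDataset, train_frac: float = 0.7, seed: int = 0
) -> tuple[SpectralDataset, SpectralDataset]:
    """Uniform random split; train size = round(train_frac * n)."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be strictly between 0 and 1")
    n = d.n_spectra
    if n < 2:
        raise ValueError("need at least 2 spectra to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return d.subset(train_idx), d.subset(test_idx)


# ---------------------------------------------------------------------------
# L1 multinomial logistic model
# ---------------------------------------------------------------------------

@dataclass
class GradingModel:
    """Fitted sparse multinomial model over ordered grade classes."""

    classes: np.ndarray          # ordered class labels (floats or bin strings)
    coef: np.ndarray             # (p, K)
    intercept: np.ndarray        # (K,)
    lambda_: float
    n_iter: int = 0
    converged: bool = True
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = _class_indices(y, classes)
    Y = np.zeros((y.shape[0], classes.shape[0]))
    Y[np.arange(y.shape[0]), idx] = 1.0
    return Y


def _class_indices(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes.tolist())}
    try:
        return np.array([lut[v] for v in y.tolist()])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not among model classes") from exc


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _ordered_classes(y: np.ndarray) -> np.ndarray:
    """Ascending for numeric labels; first-seen order is not used."""
    return np.unique(y)


def lambda_max(X: np.ndarray, y: np.ndarray, classes: np.ndarray | None = None) -> float:
    """Smallest penalty at which the all-zero coefficient model is optimal.

    At B = 0 the optimal intercepts give class-frequency probabilities, so
    the stationarity condition is |X^T (Y - pbar)|/n <= lam elementwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = _ordered_classes(y) if classes is None else classes
    Y = _one_hot(y, classes)
    G = X.T @ (Y - Y.mean(axis=0)) / X.shape[0]
    return float(np.abs(G).max())


def lambda_grid(lam_max: float, n_lambdas: int = 100, ratio: float = 1e-4) -> np.ndarray:
    """Decreasing log-spaced penalty grid from lam_max down to ratio*lam_max."""
    if n_lambdas == 1:
        return np.array([lam_max])
    return lam_max * np.logspace(0.0, np.log10(ratio), n_lambdas)


def _null_model(Y: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    freq = np.clip(Y.mean(axis=0), 1e-12, None)
    b = np.log(freq)
    return np.zeros((p, Y.shape[1])), b - b.mean()


def _objective(X, Y, yi, B, b, lam) -> float:
    P = _softmax(X @ B + b)
    nll = -np.log(np.maximum(P[np.arange(X.shape[0]), yi], 1e-300)).sum() / X.shape[0]
    return nll + lam * np.abs(B).sum()


def fit_multinomial_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    classes: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
    warm_start: GradingModel | None = None,
    raise_on_fail: bool = True,
    _warn: bool = True,
) -> GradingModel:
    """Fit the L1-penalized softmax model at one penalty value.

    Monotone FISTA: each accelerated proximal step is accepted only if it
    does not increase the penalized objective, so the recorded objective
    history is non-increasing.  Convergence = relative objective change
    below *tol*; failure raises :class:`ConvergenceError` with diagnostics
    unless ``raise_on_fail`` is False.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    classes = _ordered_classes(y) if classes is None else np.asarray(classes)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes present to fit a classifier")
    n, p = X.shape
    K = classes.shape[0]
    Y = _one_hot(y, classes)
    yi = _class_indices(y, classes)

    if lam >= lambda_max(X, y, classes) - 1e-15:
        B, b = _null_model(Y, p)
        obj = _objective(X, Y, yi, B, b, lam)
        return GradingModel(classes=classes, coef=B, intercept=b, lambda_=float(lam),
                            n_iter=0, converged=True, objective_history=np.array([obj]))

    # Lipschitz bound of the multinomial log-likelihood gradient
    smax = np.linalg.norm(X, 2)
    L = 0.5 * smax**2 / n + 1e-12
    Lb = 0.5

    if warm_start is not None and warm_start.coef.shape == (p, K):
        Bx, bx = warm_start.coef.copy(), warm_start.intercept.copy()
    else:
        Bx, bx = _null_model(Y, p)
    Bprev, bprev = Bx.copy(), bx.copy()
    Vb, vb = Bx.copy(), bx.copy()
    tk = 1.0
    obj_x = _objective(X, Y, yi, Bx, bx, lam)
    history = [obj_x]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = _softmax(X @ Vb + vb)
        R = (P - Y) / n
        Z = Vb - (X.T @ R) / L
        Z = np.sign(Z) * np.maximum(np.abs(Z) - lam / L, 0.0)
        zb = vb - R.sum(axis=0) / Lb
        obj_z = _objective(X, Y, yi, Z, zb, lam)
        Bprev, bprev = Bx, bx
        if obj_z <= obj_x:           # monotone acceptance
            Bx, bx, obj_new = Z, zb, obj_z
        else:
            obj_new = obj_x
        tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        Vb = Bx + (tk / tn) * (Z - Bx) + ((tk - 1.0) / tn) * (Bx - Bprev)
        vb = bx + (tk / tn) * (zb - bx) + ((tk - 1.0) / tn) * (bx - bprev)
        tk = tn
        history.append(obj_new)
        if abs(history[-2] - obj_new) < tol * max(1.0, abs(obj_new)):
            converged = True
            break
        obj_x = obj_new

    if not converged:
        msg = (f"multinomial LASSO did not converge at lam={lam:.3g}: "
               f"{max_iter} iterations, last objective change "
               f"{abs(history[-2] - history[-1]):.3g} (tol {tol:.1g})")
        if raise_on_fail:
            raise ConvergenceError(msg)
        if _warn:
            logger.warning(msg)
        else:
            logger.debug(msg)

    return GradingModel(classes=classes, coef=Bx, intercept=bx, lambda_=float(lam),
                        n_iter=it, converged=converged,
                        objective_history=np.asarray(history))


def predict_proba(model: GradingModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"design matrix has {X.shape[-1]} columns; model expects {model.coef.shape[0]}")
    return _softmax(X @ model.coef + model.intercept)


def predict_classes(model: GradingModel, X: np.ndarray) -> np.ndarray:
    """Argmax-probability class per row; ties break toward the lower grade.

    Classes are stored in ascending order and ``argmax`` returns the first
    maximum, so exact ties resolve to the less-diseased grade.
    """
    P = predict_proba(model, X)
    return model.classes[np.argmax(P, axis=1)]


def multinomial_deviance(model: GradingModel, X: np.ndarray, y: np.ndarray) -> float:
    """-2 * sum_i log phat(y_i | x_i), probabilities floored at 1e-10."""
    P = predict_proba(model, X)
    idx = _class_indices(np.asarray(y), model.classes)
    probs = np.maximum(P[np.arange(len(idx)), idx], 1e-10)
    return float(-2.0 * np.log(probs).sum())


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Cross-validated deviance profile along a decreasing penalty grid."""

    lambdas: np.ndarray          # decreasing
    mean_deviance: np.ndarray    # per-observation mean held-out deviance
    se_deviance: np.ndarray      # standard error across folds
    fold_deviance: np.ndarray    # (folds, n_lambdas)
    lambda_min: float
    lambda_1se: float


def _fit_path(X, y, classes, lambdas, tol, max_iter):
    models = []
    warm = None
    n_unconverged = 0
    for lam in lambdas:
        warm = fit_multinomial_lasso(X, y, lam, classes=classes, tol=tol,
                                     max_iter=max_iter, warm_start=warm,
                                     raise_on_fail=False, _warn=False)
        n_unconverged += not warm.converged
        models.append(warm)
    if n_unconverged:
        logger.info("penalty path: %d of %d fits stopped at the iteration cap "
                    "(objective change near tol)", n_unconverged, len(lambdas))
    return models


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    *,
    n_lambdas: int = 100,
    ratio: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 400,
) -> CVResult:
    """Stratified k-fold CV over the penalty path with the 1-SE rule.

    Grid: ``n_lambdas`` log-spaced values descending from the data's
    lam_max.  The per-penalty score is the across-fold mean of each fold's
    per-observation held-out deviance; lambda_1se is the largest penalty
    whose mean is within one standard error of the minimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} observations for {folds}-fold CV")
    classes = _ordered_classes(y)
    counts = pd.Series(y).value_counts()
    rare = counts[counts < folds]
    if len(rare):
        raise ValueError(
            f"classes rarer than the fold count {folds}: {dict(rare)}; "
            "bin the grades or reduce folds")

    lambdas = lambda_grid(lambda_max(X, y, classes), n_lambdas, ratio)
    yi = _class_indices(y, classes)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_dev = np.empty((folds, lambdas.size))
    for f, (tr, te) in enumerate(skf.split(X, yi)):
        models = _fit_path(X[tr], y[tr], classes, lambdas, tol, max_iter)
        for j, m in enumerate(models):
            fold_dev[f, j] = multinomial_deviance(m, X[te], y[te]) / te.size

    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean_dev))
    threshold = mean_dev[i_min] + se_dev[i_min]
    i_1se = int(np.flatnonzero(mean_dev <= threshold)[0])  # grid is decreasing
    logger.info("CV: lambda_min=%.4g (dev %.4g), lambda_1se=%.4g (dev %.4g)",
                lambdas[i_min], mean_dev[i_min], lambdas[i_1se], mean_dev[i_1se])
    return CVResult(lambdas=lambdas, mean_deviance=mean_dev, se_deviance=se_dev,
                    fold_deviance=fold_dev, lambda_min=float(lambdas[i_min]),
                    lambda_1se=float(lambdas[i_1se]))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = true label, columns = predicted."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.labels)
        if self.counts.shape != (K, K):
            raise ValueError(f"counts shape {self.counts.shape} != ({K}, {K})")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(y_true: Sequence, y_pred: Sequence, ordered_labels: Sequence) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.asarray(ordered_labels)
    ti = _class_indices(y_true, labels)
    pi = _class_indices(y_pred, labels)
    counts = np.zeros((labels.size, labels.size), dtype=int)
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(labels=tuple(labels.tolist()), counts=counts)


def classification_rate(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified observations: trace / n."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.n


def coefficient_map(model: GradingModel, axis: np.ndarray | None = None) -> pd.DataFrame:
    """Signed per-channel effect table for plotting red/green/white bands.

    One row per (channel, class).  ``sign`` is "green" for positive
    coefficients (intensity increase raises the class likelihood), "red"
    for negative, "white" for exact zeros.
    """
    p, K = model.coef.shape
    wn = np.arange(p, dtype=float) if axis is None else np.asarray(axis, dtype=float)
    if wn.size != p:
        raise ValueError("axis length does not match the coefficient rows")
    rows = []
    for k, cls in enumerate(model.classes.tolist()):
        for j in range(p):
            c = model.coef[j, k]
            rows.append((wn[j], cls, c, "white" if c == 0 else ("green" if c > 0 else "red")))
    return pd.DataFrame(rows, columns=["wavenumber", "class", "coefficient", "sign"])


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

@dataclass
class GradingReport:
    """Outcome of one grading experiment."""

    response: str
    evaluation: str              # "test" (held-out) or "train" (self-prediction)
    scheme: str | None
    strain: str | None
    cv: CVResult
    model: GradingModel
    matrix: ConfusionMatrix
    rate: float
    n_train: int
    n_eval: int


def _response_column(response: str) -> str:
    if response not in ("fibrosis", "pneumonitis"):
        raise ValueError(f"response must be fibrosis|pneumonitis, got {response!r}")
    return f"{response}_grade"


def run_grading_experiment(
    d: SpectralDataset,
    response: str = "fibrosis",
    scheme: BinningScheme | None = None,
    strain: str | None = None,
    train_frac: float | None = None,
    seed: int = 0,
    folds: int = 10,
    *,
    n_lambdas: int = 100,
    cv_tol: float = 1e-6,
    cv_max_iter: int = 400,
    fit_tol: float = 1e-7,
    fit_max_iter: int = 5000,
) -> GradingReport:
    """Optional strain subset -> optional binning -> optional split ->
    CV penalty selection (1-SE) on the training portion -> final fit ->
    confusion matrix and classification rate on the evaluation portion.

    Without a split, the model is evaluated by self-prediction on its own
    training data and the report is labeled accordingly.
    """
    col = _response_column(response)
    if strain is not None:
        mask = (d.metadata["strain"] == strain).to_numpy()
        if not mask.any():
            raise ValueError(f"strain filter {strain!r} excludes every spectrum")
        d = d.subset(mask)

    if train_frac is not None:
        train, evalset = split_train_test(d, train_frac, seed)
        evaluation = "test"
    else:
        train, evalset = d, d
        evaluation = "train"

    def labels_of(ds: SpectralDataset) -> np.ndarray:
        g = ds.metadata[col].to_numpy(dtype=float)
        if scheme is None:
            return g
        return np.asarray(bin_grades(g, scheme), dtype=object)

    y_train = labels_of(train)
    y_eval = labels_of(evalset)
    if scheme is None:
        ordered = np.unique(np.concatenate([y_train, y_eval]))
    else:
        present = set(y_train.tolist()) | set(y_eval.tolist())
        ordered = np.asarray([l for l in scheme.labels if l in present], dtype=object)

    cv = cv_select_lambda(train.matrix, y_train, folds=folds, seed=seed,
                          n_lambdas=n_lambdas, tol=cv_tol, max_iter=cv_max_iter)
    model = fit_multinomial_lasso(train.matrix, y_train, cv.lambda_1se,
                                  classes=ordered, tol=fit_tol,
                                  max_iter=fit_max_iter, raise_on_fail=False)
    y_pred = predict_classes(model, evalset.matrix)
    cm = confusion_matrix(y_eval, y_pred, ordered)
    rate = classification_rate(cm)
    logger.info("experiment %s/%s/%s: CR=%.3f on %s set (n=%d, lambda=%.4g, nnz=%d)",
                response, scheme.name if scheme else "none", strain or "all",
                rate, evaluation, cm.n, model.lambda_, model.n_nonzero)
    return GradingReport(response=response, evaluation=evaluation,
                         scheme=scheme.name if scheme else None, strain=strain,
                         cv=cv, model=model, matrix=cm, rate=rate,
                         n_train=train.n_spectra, n_eval=evalset.n_spectra)
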