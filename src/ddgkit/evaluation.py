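"""Antisymmetry-aware evaluation suite for ΔΔG predictors.

Regression quality is summarised by the Pearson correlation γ, the root mean
square error σ (kcal/mol) and the coefficient of determination
R² = 1 − SSE/SST (which can be negative; it is not a squared correlation).
Each of γ and σ is reported over all records, the direct subset and the
reverse subset.  Antisymmetry is summarised by γ_dir,rev — the Pearson
correlation between the paired direct and reverse predictions, ideally −1 —
and δ, the mean of the per-pair prediction sums, ideally 0.

The distributional similarity of two feature samples is measured by the
biased MMD² V-statistic under an RBF kernel (diagonal terms included, exactly
as the estimator is usually printed), and the significance of a difference
between two dependent correlations sharing one variable by Steiger's Z with a
one-tailed p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics.pairwise import rbf_kernel


@dataclass
class EvaluationReport:
    """All headline metrics over an augmented, paired prediction set."""

    gamma_all: float
    gamma_dir: float
    gamma_rev: float
    sigma_all: float
    sigma_dir: float
    sigma_rev: float
    r_squared: float
    gamma_dir_rev: float
    delta: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MMDResult:
    mmd2: float
    gamma: float  # RBF kernel bandwidth parameter (exp(-gamma * ||x-y||^2))
    m: int
    n: int


@dataclass
class SteigerResult:
    z: float
    p_one_tailed: float
    r1y: float
    r2y: float
    r12: float
    n: int


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient, computed from the textbook formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    dx, dy = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(dx * dx) * np.sum(dy * dy))
    if denom == 0:
        raise ValueError("zero variance input")
    return float(np.sum(dx * dy) / denom)


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def r_squared(pred: np.ndarray, truth: np.ndarray) -> float:
    """Coefficient of determination 1 − SSE/SST between prediction and truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    sst = np.sum((truth - truth.mean()) ** 2)
    if sst == 0:
        raise ValueError("zero variance in true labels; R^2 undefined")
    sse = np.sum((pred - truth) ** 2)
    return float(1.0 - sse / sst)


def regression_metrics(pred, truth) -> tuple[float, float, float]:
    """(γ, σ, R²) between predictions and true values."""
    return pearson(pred, truth), rmse(pred, truth), r_squared(pred, truth)


def antisymmetry_metrics(pred_dir, pred_rev) -> tuple[float, float]:
    """(γ_dir,rev, δ) over aligned per-pair predictions.

    A perfectly antisymmetric predictor gives (−1, 0).
    """
    pred_dir = np.asarray(pred_dir, dtype=float)
    pred_rev = np.asarray(pred_rev, dtype=float)
    if pred_dir.shape != pred_rev.shape:
        raise ValueError("direct/reverse predictions must pair up 1:1")
    gamma = pearson(pred_dir, pred_rev)
    delta = float(np.mean(pred_dir + pred_rev))
    return gamma, delta


def evaluate_predictions(
    pred_dir, truth_dir, pred_rev, truth_rev
) -> EvaluationReport:
    """Full paired evaluation: all/direct/reverse γ and σ, R², γ_dir,rev, δ."""
    pred_dir = np.asarray(pred_dir, dtype=float)
    pred_rev = np.asarray(pred_rev, dtype=float)
    truth_dir = np.asarray(truth_dir, dtype=float)
    truth_rev = np.asarray(truth_rev, dtype=float)
    pred_all = np.concatenate([pred_dir, pred_rev])
    truth_all = np.concatenate([truth_dir, truth_rev])
    g_all, s_all, r2 = regression_metrics(pred_all, truth_all)
    g_dirrev, delta = antisymmetry_metrics(pred_dir, pred_rev)
    return EvaluationReport(
        gamma_all=g_all,
        gamma_dir=pearson(pred_dir, truth_dir),
        gamma_rev=pearson(pred_rev, truth_rev),
        sigma_all=s_all,
        sigma_dir=rmse(pred_dir, truth_dir),
        sigma_rev=rmse(pred_rev, truth_rev),
        r_squared=r2,
        gamma_dir_rev=g_dirrev,
        delta=delta,
        n=len(pred_all),
    )


def mmd2_rbf(X: np.ndarray, Y: np.ndarray, gamma: float | None = None) -> MMDResult:
    """Biased MMD² between two samples under an RBF kernel.

    Implements the V-statistic with all diagonal terms included:
    mean k(x,x') + mean k(y,y') − 2 mean k(x,y).  The kernel parameter
    defaults to 1/dimension (the sklearn RBF default).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("samples must share dimensionality")
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    kxx = rbf_kernel(X, X, gamma=gamma)
    kyy = rbf_kernel(Y, Y, gamma=gamma)
    kxy = rbf_kernel(X, Y, gamma=gamma)
    mmd2 = float(kxx.mean() + kyy.mean() - 2.0 * kxy.mean())
    return MMDResult(mmd2=mmd2, gamma=gamma, m=len(X), n=len(Y))


def steiger_p_from_z(z: float) -> float:
    """One-tailed (upper) p-value for a Steiger Z score."""
    return float(stats.norm.sf(z))


def steiger_z(r1y: float, r2y: float, r12: float, n: int) -> SteigerResult:
    """Steiger's Z test for two dependent correlations sharing one variable.

    ``r1y`` and ``r2y`` are the two correlations with the shared target,
    ``r12`` the correlation between the two competing predictors, ``n`` the
    sample size.  Fisher-z transformed difference scaled by the dependent
    covariance term; p is one-tailed upper (``p = 0.5`` at ``z = 0``).
    """
    for name, r in (("r1y", r1y), ("r2y", r2y), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1, z2 = np.arctanh(r1y), np.arctanh(r2y)
    rm = 0.5 * (r1y + r2y)
    rm2 = rm * rm
    cov = (r12 * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r12 * r12)) / (
        (1.0 - rm2) ** 2
    )
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    return SteigerResult(
        z=float(z),
        p_one_tailed=steiger_p_from_z(float(z)),
        r1y=r1y,
        r2y=r2y,
        r12=r12,
        n=n,
    )


def binned_calibration(pred, truth, bins: int = 10) -> list[dict]:
    """Equal-count calibration bins sorted by the true values.

    Rows are sorted by truth and split into ``bins`` groups of equal count
    (any remainder spread one-per-bin over the leading bins); each bin
    reports the mean prediction, mean truth, and the standard error of the
    residuals (pred − truth).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n = len(pred)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if not 1 <= bins <= n:
        raise ValueError(f"bins must be in [1, {n}]")
    order = np.argsort(truth, kind="stable")
    base, extra = divmod(n, bins)
    out = []
    start = 0
    for b in range(bins):
        size = base + (1 if b < extra else 0)
        idx = order[start:start + size]
        start += size
        resid = pred[idx] - truth[idx]
        se = float(np.std(resid, ddof=1) / np.sqrt(size)) if size > 1 else 0.0
        out.append(
            {
                "bin": b,
                "n": int(size),
                "mean_pred": float(pred[idx].mean()),
                "mean_truth": float(truth[idx].mean()),
                "residual_se": se,
            }
        )
    return out
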