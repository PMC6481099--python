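"""Evaluation statistics for assay quantification.

Accuracy is summarized by the normalized mean absolute error,

    NMAE% = 100 * mean(|estimated - actual|) / range of value,

precision by the coefficient of determination of the
estimated-versus-actual ordinary-least-squares line (slope 1 and
intercept 0 mean a perfect match), and instrument repeatability by the
coefficient of variation, CV% = 100 * sd / mean.  A correlation-matrix
principal component analysis with Kaiser retention (eigenvalue > 1)
profiles the structure of a pixels-by-channels intensity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError, DegenerateInputError, NumericalError

__all__ = [
    "EvaluationReport",
    "PCAResult",
    "nmae",
    "coefficient_of_variation",
    "fit_estimated_vs_actual",
    "pca_profile",
    "evaluate",
]


def nmae(
    estimates: np.ndarray, actuals: np.ndarray, value_range: float | None = None
) -> float:
    """Normalized mean absolute error in percent.

    ``value_range`` defaults to ``max(actuals) - min(actuals)``; pass the
    full design range explicitly when evaluating a subset of levels.
    """
    est = np.asarray(estimates, dtype=np.float64)
    act = np.asarray(actuals, dtype=np.float64)
    if est.shape != act.shape or est.size < 1:
        raise ContractError("estimates and actuals must be equal-length, nonempty")
    if value_range is None:
        value_range = float(np.ptp(act))
    if value_range <= 0.0:
        raise DegenerateInputError("value range for normalization must be positive")
    return float(100.0 * np.mean(np.abs(est - act)) / value_range)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Coefficient of variation in percent (sample sd, n-1 denominator)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ContractError("CV needs at least two values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise DegenerateInputError("CV undefined for zero mean")
    return float(100.0 * np.std(v, ddof=1) / mean)


def fit_estimated_vs_actual(
    estimates: np.ndarray, actuals: np.ndarray
) -> tuple[float, float, float]:
    """OLS line of estimated on actual values: ``(slope, intercept, R2)``."""
    est = np.asarray(estimates, dtype=np.float64)
    act = np.asarray(actuals, dtype=np.float64)
    if est.shape != act.shape or est.size < 3:
        raise ContractError("need at least 3 paired points")
    if np.ptp(act) == 0.0:
        raise NumericalError("actual values are all equal; line fit is degenerate")
    res = stats.linregress(act, est)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy/precision summary of one quantification run."""

    nmae_percent: float
    r_squared: float
    slope: float
    intercept: float
    n_pixels: int
    value_range: float
    excluded_levels: tuple[float, ...] = ()
    per_level: pd.DataFrame | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {
            "nmae_percent": self.nmae_percent,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_pixels": self.n_pixels,
            "value_range": self.value_range,
            "excluded_levels": list(self.excluded_levels),
        }
        if self.per_level is not None:
            d["per_level"] = self.per_level.to_dict(orient="records")
        return d


def evaluate(
    estimates: np.ndarray,
    actuals: np.ndarray,
    value_range: float | None = None,
    excluded_levels: tuple[float, ...] = (),
) -> EvaluationReport:
    """Full evaluation: NMAE, estimated-vs-actual line, per-level summaries."""
    est = np.asarray(estimates, dtype=np.float64)
    act = np.asarray(actuals, dtype=np.float64)
    if value_range is None:
        value_range = float(np.ptp(act))
    slope, intercept, r2 = fit_estimated_vs_actual(est, act)
    per_level = (
        pd.DataFrame({"level": act, "estimate": est})
        .groupby("level", as_index=False)["estimate"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             n="count")
    )
    return EvaluationReport(
        nmae_percent=nmae(est, act, value_range),
        r_squared=r2,
        slope=slope,
        intercept=intercept,
        n_pixels=int(est.size),
        value_range=float(value_range),
        excluded_levels=tuple(excluded_levels),
        per_level=per_level,
    )


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA with Kaiser retention."""

    eigenvalues: np.ndarray  # all, descending
    explained_percent: np.ndarray  # all, descending
    loadings: pd.DataFrame  # variables x retained components
    n_retained: int
    dropped: tuple[str, ...] = ()

    @property
    def n_variables(self) -> int:
        return self.eigenvalues.size


def pca_profile(
    matrix: np.ndarray | pd.DataFrame, names: list[str] | None = None
) -> PCAResult:
    """Principal component profile of a pixels-by-channels matrix.

    Columns are standardized to z-scores, the correlation matrix is
    eigendecomposed, loadings are eigenvectors scaled by the square root
    of their eigenvalue, and components with eigenvalue > 1 are retained
    (Kaiser criterion).  Constant columns carry no correlation structure
    and are dropped with a warning.  The explained percentage of
    component k is ``100 * eigenvalue_k / n_variables``.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        data = matrix.to_numpy(dtype=np.float64)
    else:
        data = np.asarray(matrix, dtype=np.float64)
        if names is None:
            names = [f"var{i}" for i in range(data.shape[1])]
    if data.ndim != 2 or data.shape[0] < 2:
        raise DegenerateInputError("PCA needs a 2-D matrix with at least 2 rows")

    sd = data.std(axis=0, ddof=1)
    keep = sd > 0.0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant column(s) from PCA", stacklevel=2
        )
    data = data[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    if data.shape[1] < 1:
        raise DegenerateInputError("no non-constant columns left for PCA")

    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    corr = (z.T @ z) / (data.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    n_retained = int(np.sum(eigvals > 1.0))
    retained = max(n_retained, 1)  # always expose at least the leading component
    load = eigvecs[:, :retained] * np.sqrt(eigvals[:retained])
    # sign convention: the largest-magnitude loading of each component is positive
    for j in range(retained):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    loadings = pd.DataFrame(
        load, index=names, columns=[f"PC{j + 1}" for j in range(retained)]
    )
    return PCAResult(
        eigenvalues=eigvals,
        explained_percent=100.0 * eigvals / eigvals.size,
        loadings=loadings,
        n_retained=n_retained,
        dropped=dropped,
    )
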