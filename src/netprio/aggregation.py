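"""Correlation-aware aggregation of log-ORs / AUCs across traits and databases.

Each method yields one observation ``b_i`` (a log odds ratio or an AUC)
per trait x drug-database cell, ``m = n_traits * n_databases`` in all.
The overall estimate is the unweighted mean

    b_bar = (1/m) * sum_i b_i,

whose variance accounts for the correlation between cells,

    var(b_bar) = 1' S R S 1 / m^2,

with ``S`` the diagonal matrix of standard errors and ``R`` the m x m
correlation matrix formed as the Kronecker product of the
database-level and trait-level correlation matrices (database-major
index order: all traits of database 1, then all traits of database 2,
and so on).  Differences between two methods are tested with

    var(b1_bar - b2_bar) = var(b1_bar) + var(b2_bar) - 2 cov,
    cov ~= r * (1' S1 R S2 1 / m^2),

where ``r`` is the empirical Pearson correlation between the two
observation vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ObservationVector",
    "CorrelationModel",
    "AggregateResult",
    "exchangeable_corr",
    "validate_correlation",
    "kronecker_correlation",
    "overall_estimate",
    "overall_variance",
    "difference_test",
    "fill_fallback_se",
]

PSD_TOL = 1e-8


def exchangeable_corr(n: int, rho: float) -> np.ndarray:
    """Exchangeable (compound-symmetry) correlation matrix."""
    if not (-1.0 / max(n - 1, 1) <= rho <= 1.0):
        raise ValueError(f"rho={rho} is not a valid exchangeable correlation for n={n}")
    return np.full((n, n), rho) + (1.0 - rho) * np.eye(n)


def validate_correlation(R: np.ndarray, name: str = "R") -> np.ndarray:
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have unit diagonal")
    return R


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eigh(R)
    lam = np.clip(lam, 0.0, None)
    out = (V * lam) @ V.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class ObservationVector:
    """m = traits x databases observations for one method.

    ``index`` carries (trait, database) labels in database-major order,
    matching the Kronecker convention of :class:`CorrelationModel`.
    """

    b: np.ndarray
    se: np.ndarray
    index: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, float)
        self.se = np.asarray(self.se, float)
        if self.b.shape != self.se.shape or self.b.ndim != 1:
            raise ValueError("b and se must be 1-d arrays of equal length")
        if np.any(self.se[np.isfinite(self.se)] < 0):
            raise ValueError("standard errors must be nonnegative")
        if self.index and len(self.index) != len(self.b):
            raise ValueError("index length does not match observations")

    @property
    def m(self) -> int:
        return len(self.b)


@dataclass
class CorrelationModel:
    """Database x trait correlation structure for one observation layout."""

    R_db: np.ndarray
    R_trait: np.ndarray

    def __post_init__(self) -> None:
        self.R_db = validate_correlation(self.R_db, "R_db")
        self.R_trait = validate_correlation(self.R_trait, "R_trait")

    @property
    def R(self) -> np.ndarray:
        return kronecker_correlation(self.R_db, self.R_trait)

    @property
    def m(self) -> int:
        return self.R_db.shape[0] * self.R_trait.shape[0]


@dataclass(frozen=True)
class AggregateResult:
    b_bar: float
    var_b_bar: float
    overall_or: float | None = None

    @property
    def se(self) -> float:
        return math.sqrt(self.var_b_bar)

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.isf((1.0 - level) / 2.0)
        return self.b_bar - zq * self.se, self.b_bar + zq * self.se


def kronecker_correlation(R_db: np.ndarray, R_trait: np.ndarray) -> np.ndarray:
    """R = R_db (x) R_trait, in database-major / trait-minor index order."""
    R_db = validate_correlation(R_db, "R_db")
    R_trait = validate_correlation(R_trait, "R_trait")
    m = R_db.shape[0] * R_trait.shape[0]
    if m > 100_000:
        raise ValueError(f"Kronecker correlation of dimension {m} is too large")
    return np.kron(R_db, R_trait)


def overall_estimate(obs: ObservationVector, is_log_or: bool = True) -> AggregateResult:
    """Unweighted mean of the observation vector (variance filled separately)."""
    if obs.m == 0:
        raise ValueError("empty observation vector")
    b_bar = float(np.mean(obs.b))
    return AggregateResult(
        b_bar=b_bar, var_b_bar=float("nan"),
        overall_or=math.exp(b_bar) if is_log_or else None,
    )


def _checked_R(obs_m: int, model: CorrelationModel) -> np.ndarray:
    R = model.R
    if R.shape[0] != obs_m:
        raise ValueError(
            f"correlation model dimension {R.shape[0]} does not match m={obs_m}"
        )
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < -PSD_TOL:
        warnings.warn(
            f"correlation matrix not PSD (min eigenvalue {min_eig:.3e}); "
            "nearest-PSD projection applied"
        )
        R = _nearest_psd(R)
    return R


def overall_variance(obs: ObservationVector, model: CorrelationModel) -> float:
    """var(b_bar) = 1' S R S 1 / m^2 with S = diag(se)."""
    R = _checked_R(obs.m, model)
    se = obs.se
    if np.any(~np.isfinite(se)):
        raise ValueError("non-finite standard errors; apply fill_fallback_se first")
    var = float(se @ R @ se) / obs.m**2
    return max(var, 0.0)


def aggregate(
    obs: ObservationVector,
    model: CorrelationModel,
    is_log_or: bool = True,
) -> AggregateResult:
    """Overall estimate with its correlation-aware variance."""
    est = overall_estimate(obs, is_log_or=is_log_or)
    return AggregateResult(
        b_bar=est.b_bar,
        var_b_bar=overall_variance(obs, model),
        overall_or=est.overall_or,
    )


def difference_test(
    obs1: ObservationVector,
    obs2: ObservationVector,
    model: CorrelationModel,
) -> tuple[float, float]:
    """z and two-sided p for the difference of two overall estimates.

    The covariance of the two means is approximated by scaling the
    cross quadratic form with the empirical Pearson correlation between
    the paired observation vectors (finite pairs only, listwise).  A
    nonpositive variance of the difference raises with diagnostics
    rather than being clamped.
    """
    if obs1.m != obs2.m:
        raise ValueError("observation vectors must share the same layout")
    if obs1.index and obs2.index and obs1.index != obs2.index:
        raise ValueError("observation vectors must share the same index order")
    if obs1.m < 3:
        raise ValueError("empirical correlation needs at least 3 observations")
    R = _checked_R(obs1.m, model)
    finite = np.isfinite(obs1.b) & np.isfinite(obs2.b)
    b1, b2 = obs1.b[finite], obs2.b[finite]
    if len(b1) < 3:
        raise ValueError("fewer than 3 complete observation pairs")
    if np.std(b1) == 0 or np.std(b2) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(b1, b2)[0, 1])
    v1 = overall_variance(obs1, model)
    v2 = overall_variance(obs2, model)
    cov = r * float(obs1.se @ R @ obs2.se) / obs1.m**2
    var_diff = v1 + v2 - 2.0 * cov
    diff = float(np.mean(obs1.b) - np.mean(obs2.b))
    if var_diff <= 0:
        if diff == 0.0:
            return 0.0, 1.0
        raise ValueError(
            f"nonpositive variance of difference ({var_diff:.3e}); "
            f"var1={v1:.3e} var2={v2:.3e} cov={cov:.3e} r={r:.3f}"
        )
    z = diff / math.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def fill_fallback_se(obs: ObservationVector) -> ObservationVector:
    """Replace undefined SEs of fallback (OR := 1) observations.

    Observations whose odds ratio was set to 1 because no prioritized
    gene was a target contribute b = 0 but have no defined standard
    error; they are assigned the maximum finite SE within the method's
    vector (conservative weighting without dropping cells).
    """
    se = obs.se.copy()
    bad = ~np.isfinite(se)
    if bad.any():
        finite = se[~bad]
        if finite.size == 0:
            raise ValueError("no finite standard error to impute from")
        se[bad] = finite.max()
    return ObservationVector(b=obs.b.copy(), se=se, index=list(obs.index))
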