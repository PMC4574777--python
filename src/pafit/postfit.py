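"""Uncertainty quantification and attachment-exponent estimation.

The observed information of the kernel likelihood has the low-rank-plus-
diagonal structure ``D = B + U C U^T`` with diagonal ``B`` and ``C``, so its
inverse (whose diagonal gives the asymptotic variances of the estimated
kernel) can be computed three ways:

* ``full_inverse`` — dense inversion of ``D``, O(K^3);
* ``woodbury`` — the Woodbury identity
  ``D^-1 = B^-1 - B^-1 U (C^-1 + U^T B^-1 U)^-1 U^T B^-1``, O(K T^2), a
  large saving when the number of time-steps T is much smaller than the
  number of degrees K;
* ``B_only`` — drop the low-rank part entirely: ``v_k = A_k^2 / sum_t
  m_k(t)``, O(K).

Since the kernel is only identifiable up to scale the full information
matrix is singular along the scale direction; ``full_inverse`` and
``woodbury`` therefore hold the reference bin fixed (its row and column are
deleted and its variance reported as 0).

The attachment exponent of the log-linear model ``A_k = k^alpha`` is
recovered from the nonparametric estimate either by weighted least squares
on ``(log k, log A_k)`` with weights ``1 / var(log A_k)``, or by fitting the
slope ``alpha + 1`` of the cumulative kernel ``Pi(k) = sum_{j<=k} A_j`` on
the log-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy import stats as sps

from .core import FitResult
from .netevents import SuffStats
from .results import KernelEstimate

__all__ = [
    "VarianceReport",
    "ExponentFit",
    "approx_variances",
    "confidence_intervals",
    "fit_exponent_wls",
    "fit_exponent_cumulative",
    "operation_count",
]

_METHODS = ("B_only", "woodbury", "full_inverse")


@dataclass(frozen=True)
class VarianceReport:
    """Per-degree variances of an estimated kernel (NaN where undefined)."""

    v: np.ndarray
    method: str
    level: float = 0.95

    def sd_log(self, A_hat: np.ndarray) -> np.ndarray:
        """Standard deviation of ``log A_hat``: ``sqrt(v) / A_hat``."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(self.v) / A_hat


@dataclass(frozen=True)
class ExponentFit:
    """Estimated attachment exponent of the log-linear kernel ``k^alpha``."""

    alpha: float
    intercept: float
    se_alpha: float
    method: str


def operation_count(method: str, K: int, T: int) -> int:
    """Dominant floating-point operation count of each variance method."""
    if method == "B_only":
        return K
    if method == "woodbury":
        return K * T * T + T**3
    if method == "full_inverse":
        return K**3
    raise ValueError(f"unknown method {method!r}")


def approx_variances(fit: FitResult, stats: SuffStats, method: str = "B_only") -> VarianceReport:
    """Variances of the fitted kernel values from the observed information.

    Computed at bin granularity on the normalised scale of ``fit.estimate``
    and expanded back to degrees.  Requires a converged, unregularised fit
    (the curvature is that of the plain likelihood).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if not fit.converged:
        raise ValueError("fit did not converge; variances would be meaningless")
    if fit.config.lambda_ratio > 0:
        raise ValueError("variance approximation applies to the unpenalised fit")

    bins = fit.bins
    Mbt = np.asarray(bins.aggregate(stats.m_k_t).todense(), dtype=float)
    Nbt = np.asarray(bins.aggregate(stats.n_k_t).todense(), dtype=float)
    m_t = stats.m_t.astype(float)
    Mb = Mbt.sum(axis=1)
    omega = fit.omega
    sup = (Mb > 0) & (omega > 0)

    v_bin = np.full(bins.B, np.nan)
    if method == "B_only":
        v_bin[sup] = omega[sup] ** 2 / Mb[sup]
    else:
        ref_bin = int(bins.bin_of(np.array([fit.estimate.reference_degree(
            fit.config.ref_degree)]))[0])
        free = sup.copy()
        free[ref_bin] = False
        idx = np.flatnonzero(free)
        if idx.size:
            b_diag = Mb[idx] / omega[idx] ** 2
            S_t = omega @ Nbt  # normaliser includes every bin, ref too
            U = Nbt[idx]
            c_diag = -m_t / S_t**2
            if method == "full_inverse":
                D = np.diag(b_diag) + (U * c_diag) @ U.T
                v_bin[idx] = np.diag(np.linalg.inv(D))
            else:  # woodbury
                Binv = 1.0 / b_diag
                core = np.diag(1.0 / c_diag) + U.T @ (Binv[:, None] * U)
                W = np.linalg.solve(core, (Binv[:, None] * U).T)
                v_bin[idx] = Binv - np.einsum("kt,tk->k", Binv[:, None] * U, W)
        v_bin[ref_bin] = 0.0  # fixed by the normalisation convention

    v = bins.expand(v_bin)
    return VarianceReport(v=v, method=method)


def confidence_intervals(
    estimate: KernelEstimate,
    var: VarianceReport,
    level: float = 0.95,
) -> KernelEstimate:
    """Normal-approximation intervals built on the log scale.

    ``exp(log A_hat +/- z * sd(log A_hat))`` with
    ``var(log A_hat) = v / A_hat^2``; bounds are positive by construction.
    """
    z = sps.norm.ppf(0.5 + level / 2.0)
    sd = var.sd_log(estimate.A_hat)
    with np.errstate(invalid="ignore"):
        lo = estimate.A_hat * np.exp(-z * sd)
        hi = estimate.A_hat * np.exp(z * sd)
    return replace(estimate, variances=var.v, ci_lower=lo, ci_upper=hi)


def _wls_points(estimate: KernelEstimate, var_log: Optional[np.ndarray]):
    mask = estimate.supported() & (estimate.degrees >= 1)
    if var_log is not None:
        mask &= np.isfinite(var_log) & (var_log > 0)
    if mask.sum() < 2:
        raise ValueError("need at least two usable degrees k >= 1")
    x = np.log(estimate.degrees[mask].astype(float))
    y = np.log(estimate.A_hat[mask])
    w = 1.0 / var_log[mask] if var_log is not None else np.ones(x.size)
    if estimate.bin_index is None:
        return x, y, w
    # a binned estimate carries one parameter per bin, not per degree:
    # collapse each bin to a single point at its mean log-degree, so wide
    # bins do not enter the regression once per member degree
    groups = estimate.bin_index[mask]
    uniq, inv = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least two usable bins")
    counts = np.bincount(inv)
    xg = np.bincount(inv, weights=x) / counts
    yg = np.bincount(inv, weights=y) / counts
    wg = np.bincount(inv, weights=w) / counts
    return xg, yg, wg


def fit_exponent_wls(
    estimate: KernelEstimate,
    var: Optional[Union[VarianceReport, np.ndarray]] = None,
) -> ExponentFit:
    """Weighted least squares for ``alpha`` in ``log A_k = alpha log k + d``.

    Weights are the inverse variances of ``log A_hat_k``
    (``var(log A_hat) = v_k / A_hat_k^2``); ``var=None`` uses equal weights.
    Degree 0 and missing degrees are excluded.
    """
    if isinstance(var, VarianceReport):
        var_log = var.sd_log(estimate.A_hat) ** 2
    elif var is not None:
        var_log = np.asarray(var, dtype=float)
    else:
        var_log = None
    x, y, w = _wls_points(estimate, var_log)
    X = np.column_stack([x, np.ones_like(x)])
    WX = X * w[:, None]
    coef, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * y), rcond=None)
    alpha, d = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    dof = max(x.size - 2, 1)
    s2 = float((w * resid**2).sum()) / dof
    cov = s2 * np.linalg.inv(X.T @ WX)
    return ExponentFit(alpha=alpha, intercept=d, se_alpha=float(np.sqrt(cov[0, 0])),
                       method="wls")


def fit_exponent_cumulative(estimate: KernelEstimate) -> ExponentFit:
    """Exponent from the cumulative kernel ``Pi(k) = sum_{j<=k} A_j``.

    Under ``A_k = k^alpha`` the cumulative function grows like
    ``k^(alpha+1)``, so the log-log slope of ``Pi`` minus one estimates
    ``alpha``.  Missing values are treated as 0 in the cumulative sum.
    """
    sup = estimate.supported()
    if sup.sum() < 2:
        raise ValueError("need at least two supported degrees")
    A = np.where(np.isfinite(estimate.A_hat), estimate.A_hat, 0.0)
    Pi = np.cumsum(A)
    mask = (estimate.degrees >= 1) & (Pi > 0)
    x = np.log(estimate.degrees[mask].astype(float))
    y = np.log(Pi[mask])
    slope, intercept = np.polyfit(x, y, 1)
    n = x.size
    resid = y - (slope * x + intercept)
    sxx = ((x - x.mean()) ** 2).sum()
    se = np.sqrt((resid @ resid) / max(n - 2, 1) / sxx) if sxx > 0 else np.nan
    return ExponentFit(alpha=float(slope - 1.0), intercept=float(intercept),
                       se_alpha=float(se), method="cumulative")
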