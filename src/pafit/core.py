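"""Nonparametric maximum-likelihood estimation of the attachment kernel.

The estimator maximises the multinomial log-likelihood

    l(A) = sum_t sum_k m_k(t) log A_k  -  sum_t m(t) log( sum_j n_j(t) A_j )

over the kernel values ``A_k`` (one shared parameter per logarithmic degree
bin), by the minorize-maximization (MM) fixed-point iteration

    A_k  <-  sum_t m_k(t)  /  sum_t [ m(t) n_k(t) / sum_j n_j(t) A_j ].

Each iteration is guaranteed not to decrease the objective, and any fixed
point is a *global* maximiser: under the reparametrisation
``beta_k = log A_k`` the objective is concave, so every stationary point is
global.  The kernel is identifiable only up to scale; the returned estimate
is normalised to 1 at a reference degree.

An optional roughness penalty ``-lambda * sum_i w_i (d2 log A)_i^2 / sum w``
(second differences of ``log A`` along the bin sequence, weighted by the
attachment-event counts) shrinks the estimate toward log-linearity.  The
penalised objective is still concave in ``beta``; it is maximised by an MM
outer loop whose separable concave surrogate is solved exactly by damped
Newton steps, preserving the monotone-ascent contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from .binning import BinScheme, make_bins
from .netevents import SuffStats
from .results import KernelEstimate

__all__ = ["FitConfig", "FitResult", "fit_pafit", "log_likelihood", "mm_update", "make_bins"]

_BETA_MIN = -60.0  # bounds on log A during penalized optimisation
_BETA_MAX = 60.0


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the maximum-likelihood fit.

    Parameters
    ----------
    B
        Number of degree bins (degree 0 always gets its own bin).
    lambda_ratio
        Regularization strength as a ratio ``r`` of the total number of
        attachment events: ``lambda = r * sum_t sum_k m_k(t)``.  ``0``
        disables the penalty; ratios up to 1 are the useful range.
    eps
        Relative-change tolerance on the (penalised) objective.
    max_iter
        Iteration cap; hitting it flags the result as not converged.
    ref_degree
        Degree whose estimate is fixed to 1 (shifted to the smallest
        supported degree if it carries no attachment events).
    """

    B: int = 100
    lambda_ratio: float = 0.0
    eps: float = 1e-5
    max_iter: int = 100_000
    ref_degree: int = 1

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.lambda_ratio < 0:
            raise ValueError("lambda_ratio must be >= 0")
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_pafit`."""

    estimate: KernelEstimate
    loglik_trace: np.ndarray
    converged: bool
    iterations: int
    config: FitConfig
    bins: BinScheme
    omega: np.ndarray  # per-bin values on the same scale as estimate.A_hat

    def __post_init__(self) -> None:
        tr = np.asarray(self.loglik_trace, dtype=float)
        object.__setattr__(self, "loglik_trace", tr)


def log_likelihood(A: Sequence[float], stats: SuffStats) -> float:
    """Multinomial log-likelihood of per-degree kernel values (constants dropped).

    ``A`` must be positive at every degree with attachment events, and the
    normalizer ``sum_j n_j(t) A_j`` positive at every step with edges;
    violations raise rather than silently returning ``-inf``.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != stats.K + 1:
        raise ValueError(f"A must have length K+1 = {stats.K + 1}")
    if not np.isfinite(A).all() or (A < 0).any():
        raise ValueError("kernel values must be finite and non-negative")
    M = stats.m_per_degree()
    if (A[M > 0] <= 0).any():
        raise ValueError("A must be positive at every degree with attachment events")
    denom = stats.n_k_t.T @ A
    if (denom[stats.m_t > 0] <= 0).any():
        raise ValueError("normalizer sum_j n_j(t) A_j vanishes at a step with edges")
    pos = M > 0
    return float(M[pos] @ np.log(A[pos]) - stats.m_t @ np.log(denom))


def _binned(stats: SuffStats, bins: BinScheme):
    """Dense per-bin count arrays: (M_b totals, M_bt, N_bt)."""
    Mbt = np.asarray(bins.aggregate(stats.m_k_t).todense(), dtype=float)
    Nbt = np.asarray(bins.aggregate(stats.n_k_t).todense(), dtype=float)
    return Mbt.sum(axis=1), Mbt, Nbt


def _binned_loglik(omega: np.ndarray, Mb: np.ndarray, Nbt: np.ndarray, m_t: np.ndarray) -> float:
    pos = Mb > 0
    denom = omega @ Nbt
    return float(Mb[pos] @ np.log(omega[pos]) - m_t @ np.log(denom))


def mm_update(
    A: Sequence[float],
    stats: SuffStats,
    bins: Optional[BinScheme] = None,
) -> np.ndarray:
    """One MM step on per-degree kernel values, at bin granularity.

    Counts are summed within bins before the update; the returned values
    are the updated per-bin parameters expanded back to degrees.  The step
    never decreases :func:`log_likelihood`.
    """
    if bins is None:
        bins = make_bins(stats.K, stats.K + 1)
    A = np.asarray(A, dtype=float)
    omega = bins.aggregate(A * np.ones(stats.K + 1)) / bins.widths  # mean within bin
    Mb, _, Nbt = _binned(stats, bins)
    new = _mm_step(omega, Mb, Nbt, stats.m_t.astype(float))
    return bins.expand(new)


def _mm_step(omega: np.ndarray, Mb: np.ndarray, Nbt: np.ndarray, m_t: np.ndarray) -> np.ndarray:
    denom = omega @ Nbt
    if (denom[m_t > 0] <= 0).any():
        raise ValueError("normalizer vanishes at a step with edges")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = Nbt @ np.where(denom > 0, m_t / denom, 0.0)
    new = np.zeros_like(omega)
    sup = Mb > 0
    new[sup] = Mb[sup] / r[sup]
    return new


def _curvature_operator(x: np.ndarray, n_cols: int, col_offset: int) -> sparse.csr_matrix:
    """Divided second-difference operator on the grid ``x`` (log degree).

    Row ``i`` measures the curvature of ``beta`` at ``x[i+1]``, scaled so
    that on an equally spaced grid it reduces to the plain second
    difference ``beta[i+2] + beta[i] - 2 beta[i+1]``; it vanishes exactly
    when ``beta`` is linear in ``x``, i.e. when the kernel is log-linear.
    Columns are embedded at ``col_offset`` into a width-``n_cols`` matrix.
    """
    n = x.size
    if n < 3:
        return sparse.csr_matrix((0, n_cols))
    x0, x1, x2 = x[:-2], x[1:-1], x[2:]
    c0 = (x2 - x0) / (2.0 * (x1 - x0))
    c2 = (x2 - x0) / (2.0 * (x2 - x1))
    data = np.column_stack([c0, -(c0 + c2), c2]).ravel()
    rows = np.repeat(np.arange(n - 2), 3)
    cols = col_offset + rows + np.tile([0, 1, 2], n - 2)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n - 2, n_cols))


def fit_pafit(
    stats: SuffStats,
    cfg: FitConfig | None = None,
    *,
    start: Optional[Sequence[float]] = None,
) -> FitResult:
    """Fit the attachment kernel by (penalised) maximum likelihood.

    Iterates the MM update from an all-ones start (or ``start``, per-bin)
    until the relative change of the objective drops below ``cfg.eps`` or
    ``cfg.max_iter`` is reached.  Bins with zero attachment events are not
    estimable without the penalty and are reported missing (NaN); with
    ``lambda_ratio > 0`` they are tied to their neighbours through the
    roughness penalty and receive finite values.
    """
    cfg = cfg or FitConfig()
    if stats.total_events <= 0:
        raise ValueError("no attachment events: every step has m(t) = 0")
    bins = make_bins(stats.K, cfg.B)
    Mb, _, Nbt = _binned(stats, bins)
    m_t = stats.m_t.astype(float)
    lam = cfg.lambda_ratio * stats.total_events

    if cfg.lambda_ratio == 0:
        omega, trace, converged, iters = _fit_mm(Mb, Nbt, m_t, cfg, start)
    else:
        omega, trace, converged, iters = _fit_penalized(Mb, Nbt, m_t, lam, cfg, start, bins)

    A = bins.expand(np.where(omega > 0, omega, np.nan))
    est = KernelEstimate(
        degrees=np.arange(stats.K + 1),
        A_hat=A,
        method=f"pafit(B={bins.B},ratio={cfg.lambda_ratio:g})",
        bin_index=bins.bin_index(),
    ).normalized(cfg.ref_degree)
    ref = est.reference_degree(cfg.ref_degree)
    scale = omega[bins.bin_of(np.array([ref]))[0]]
    return FitResult(
        estimate=est,
        loglik_trace=np.asarray(trace),
        converged=converged,
        iterations=iters,
        config=cfg,
        bins=bins,
        omega=omega / scale,
    )


def _start_omega(Mb: np.ndarray, active: np.ndarray, start, bins_B: int) -> np.ndarray:
    omega = np.zeros(bins_B)
    if start is None:
        omega[active] = 1.0
    else:
        start = np.asarray(start, dtype=float)
        if start.shape[0] != bins_B:
            raise ValueError(f"start must have one value per bin ({bins_B})")
        if (start[active] <= 0).any():
            raise ValueError("start must be positive on active bins")
        omega[active] = start[active]
    return omega


def _fit_mm(Mb, Nbt, m_t, cfg: FitConfig, start):
    sup = Mb > 0
    omega = _start_omega(Mb, sup, start, Mb.size)
    trace = [_binned_loglik(omega, Mb, Nbt, m_t)]
    converged = False
    it = 0
    while it < cfg.max_iter:
        it += 1
        omega = _mm_step(omega, Mb, Nbt, m_t)
        trace.append(_binned_loglik(omega, Mb, Nbt, m_t))
        if abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0) <= cfg.eps:
            converged = True
            break
    return omega, trace, converged, it


def _penalty_matrices(active_idx: np.ndarray, Mb: np.ndarray, bins: BinScheme):
    """Curvature operator over the active bins at degree >= 1, and weights.

    The degree-0 bin is excluded from the penalty chain (log 0 has no place
    on the log-degree axis, and no log-linear model constrains ``A_0``);
    curvature is measured against the log of each bin's representative
    degree, so the penalty is exactly zero for ``A_k = c * k^alpha``.
    """
    chain = active_idx[active_idx >= 1]
    offset = active_idx.size - chain.size  # 1 iff the degree-0 bin is active
    x = np.log(bins.representatives()[chain])
    D = _curvature_operator(x, active_idx.size, offset)
    if chain.size >= 3:
        w = Mb[chain][1:-1]
        tot = w.sum()
        w = w / tot if tot > 0 else np.full(w.size, 1.0 / max(w.size, 1))
    else:
        w = np.zeros(0)
    return D, w


def _fit_penalized(Mb, Nbt, m_t, lam, cfg: FitConfig, start, bins: BinScheme):
    # estimable bins: attachment events, or (at degree >= 1) tied in through
    # the penalty while being populated at some step
    has_nodes = Nbt.sum(axis=1) > 0
    active = (Mb > 0) | (has_nodes & (np.arange(Mb.size) >= 1))
    idx = np.flatnonzero(active)
    Mb_a, Nbt_a = Mb[idx], Nbt[idx]
    D, w = _penalty_matrices(idx, Mb, bins)
    DtW = D.T @ sparse.diags(w) @ D  # quadratic form of the penalty

    def penalty(beta):
        d2 = D @ beta
        return float(d2 @ (w * d2))

    def objective(beta):
        pos = Mb_a > 0
        denom = np.exp(beta) @ Nbt_a
        return float(Mb_a[pos] @ beta[pos] - m_t @ np.log(denom) - lam * penalty(beta))

    omega0 = _start_omega(Mb, active, start, Mb.size)
    beta = np.log(np.maximum(omega0[idx], np.exp(_BETA_MIN)))
    trace = [objective(beta)]
    converged = False
    it = 0
    while it < cfg.max_iter:
        it += 1
        beta = _surrogate_newton(beta, Mb_a, Nbt_a, m_t, lam, D, DtW, w)
        trace.append(objective(beta))
        if abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0) <= cfg.eps:
            converged = True
            break
    omega = np.zeros_like(Mb)
    omega[idx] = np.exp(beta)
    return omega, trace, converged, it


def _surrogate_newton(beta, Mb_a, Nbt_a, m_t, lam, D, DtW, w, inner_max=25, tol=1e-10):
    """Exactly maximise the separable MM surrogate of the penalised objective.

    The surrogate at the current point is
    ``Q(b) = sum Mb b - sum s_b exp(b) - lam * pen(b)`` with
    ``s_b = sum_t m(t) n_b(t) / denom_t`` evaluated at the current iterate;
    it minorises the penalised log-likelihood up to a constant, so any
    ascent on Q is ascent on the objective.  Q is smooth and concave; damped
    Newton with backtracking converges in a handful of steps.
    """
    denom = np.exp(beta) @ Nbt_a
    s = Nbt_a @ (m_t / denom)

    def Q(b):
        d2 = D @ b
        return float(Mb_a @ b - s @ np.exp(b) - lam * (d2 @ (w * d2)))

    q_old = Q(beta)
    b = beta.copy()
    for _ in range(inner_max):
        eb = np.exp(b)
        grad = Mb_a - s * eb - 2.0 * lam * (DtW @ b)
        H = np.diag(s * eb) + 2.0 * lam * DtW.toarray()
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        q_here = Q(b)
        while t > 1e-12:
            cand = np.clip(b + t * step, _BETA_MIN, _BETA_MAX)
            if Q(cand) >= q_here:
                break
            t *= 0.5
        b_new = np.clip(b + t * step, _BETA_MIN, _BETA_MAX)
        q_new = Q(b_new)
        if q_new < q_here:  # no ascent possible along the Newton direction
            break
        b = b_new
        if abs(q_new - q_here) <= tol * (abs(q_here) + 1.0):
            break
    return b if Q(b) >= q_old else beta
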