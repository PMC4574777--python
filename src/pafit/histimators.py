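"""Histogram-style attachment-kernel estimators.

Two classical nonparametric estimators, plus a corrected variant:

* **Jeong's method** — freeze the degrees of all nodes present at a chosen
  time ``T0``; count, per frozen degree ``k``, the edges arriving during a
  later window ``[T1, T1 + dT)`` that land on those nodes, and normalise by
  ``n_k(T0)``.  A single-histogram method with an inherent bias-variance
  trade-off in the choice of window.
* **Newman's method** — a weighted sum of per-step histograms
  ``A_k(t) = m_k(t) N(t) / (n_k(t) m(t))`` with weights
  ``w_k(t) = m(t) * 1{n_k(t) != 0}``, normalised by a constant that does
  not depend on ``k``.  Because large degrees only exist late in the
  growth, the k-independent normaliser systematically underestimates the
  kernel at high degree (the "waterfall" artifact).
* **corrected Newman** — the same weighted sum normalised per degree by
  ``sum_t w_k(t)``, which removes the artifact entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .binning import BinScheme
from .netevents import SuffStats, TemporalEdgeList
from .results import KernelEstimate

__all__ = ["JeongWindows", "jeong_estimate", "newman_estimate", "KernelEstimate"]


@dataclass(frozen=True)
class JeongWindows:
    """Window choice for Jeong's estimator.

    ``T0`` defines the reference population (all nodes present at ``T0``,
    degrees frozen there); edges are counted during ``[T1, T1 + dT)``.
    """

    T0: int
    T1: int
    dT: int

    def __post_init__(self) -> None:
        if not (0 <= self.T0 < self.T1):
            raise ValueError("need 0 <= T0 < T1")
        if self.dT < 1:
            raise ValueError("dT must be >= 1")


def jeong_estimate(
    net: TemporalEdgeList,
    win: JeongWindows,
    *,
    bins: Optional[BinScheme] = None,
    sources: str = "t1",
) -> KernelEstimate:
    """Jeong's single-window histogram estimate of the attachment kernel.

    ``sources`` selects which window edges are counted: ``"t1"`` (default)
    counts only edges whose source arrived in the window, per the method's
    original description ("a degree-k T0-node linked to by a T1-node");
    ``"any"`` counts every window edge landing on a T0-node.  When the
    growth process picks sources independently of degree the two differ
    only by a uniform thinning of the counts, i.e. by noise.
    """
    if win.T1 + win.dT > net.T + 1:
        raise ValueError("window [T1, T1+dT) extends past the last time-step")
    if sources not in ("any", "t1"):
        raise ValueError("sources must be 'any' or 't1'")

    frozen: dict = {v: 0 for v, a in net.node_arrivals.items() if a <= win.T0}
    if not frozen:
        raise ValueError("no T0-nodes: nothing arrives at or before T0")
    for t, _, v in net.edges:
        if t <= win.T0 and v in frozen:
            frozen[v] += 1

    t1_nodes = {v for v, a in net.node_arrivals.items()
                if win.T1 <= a < win.T1 + win.dT}
    if sources == "t1" and not t1_nodes:
        raise ValueError("no T1-nodes arrive in the window")

    window_edges = [(t, u, v) for t, u, v in net.edges if win.T1 <= t < win.T1 + win.dT]
    if not window_edges:
        raise ValueError("window contains no edges")

    K0 = max(frozen.values())
    n_k = np.zeros(K0 + 1, dtype=float)
    for k in frozen.values():
        n_k[k] += 1
    counts = np.zeros(K0 + 1, dtype=float)
    for _, u, v in window_edges:
        if v in frozen and (sources == "any" or u in t1_nodes):
            counts[frozen[v]] += 1

    if bins is not None:
        if bins.K < K0:
            raise ValueError("bin scheme does not cover the frozen degree range")
        bc = bins.aggregate(np.concatenate([counts, np.zeros(bins.K - K0)]))
        bn = bins.aggregate(np.concatenate([n_k, np.zeros(bins.K - K0)]))
        with np.errstate(divide="ignore", invalid="ignore"):
            omega = np.where(bn > 0, bc / np.maximum(bn, 1e-300), np.nan)
        A = bins.expand(omega)[: K0 + 1]
        bin_index = bins.bin_index()[: K0 + 1]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(n_k > 0, counts / np.maximum(n_k, 1e-300), np.nan)
        bin_index = None

    est = KernelEstimate(
        degrees=np.arange(K0 + 1),
        A_hat=A,
        method=f"jeong(T0={win.T0},T1={win.T1},dT={win.dT},sources={sources})",
        bin_index=bin_index,
    )
    return est.normalized()


def newman_estimate(
    stats: SuffStats,
    *,
    corrected: bool = True,
    bins: Optional[BinScheme] = None,
) -> KernelEstimate:
    """Newman's multi-histogram estimate, optionally with the normalisation fix.

    Per step, ``A_k(t) = m_k(t) N(t) / (n_k(t) m(t))`` (convention
    ``0/0 = 0``) is combined across steps with weights
    ``w_k(t) = m(t) * 1{n_k(t) != 0}``.  With ``corrected=False`` the sum is
    divided by the k-independent constant ``sum_t m(t)``; with
    ``corrected=True`` each degree is divided by its own total weight
    ``sum_t w_k(t)``.  Degrees whose total weight is zero are missing.
    """
    if not (stats.m_t > 0).any():
        raise ValueError("no step with positive m(t)")
    if bins is None:
        from .binning import make_bins

        bins = make_bins(stats.K, stats.K + 1)
    elif bins.K != stats.K:
        raise ValueError("bin scheme must cover degrees 0..K of the statistics")

    Mbt = np.asarray(bins.aggregate(stats.m_k_t).todense(), dtype=float)
    Nbt = np.asarray(bins.aggregate(stats.n_k_t).todense(), dtype=float)
    m_t = stats.m_t.astype(float)
    N_t = stats.N_t.astype(float)

    present = Nbt > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        A_kt = np.where(present, Mbt * N_t / (np.maximum(Nbt, 1e-300) * m_t), 0.0)
    w_kt = present * m_t
    weighted = (w_kt * A_kt).sum(axis=1)
    total_w = w_kt.sum(axis=1)

    if corrected:
        with np.errstate(divide="ignore", invalid="ignore"):
            omega = np.where(total_w > 0, weighted / np.maximum(total_w, 1e-300), np.nan)
    else:
        omega = np.where(total_w > 0, weighted / m_t.sum(), np.nan)

    est = KernelEstimate(
        degrees=np.arange(stats.K + 1),
        A_hat=bins.expand(omega),
        method="newman_corrected" if corrected else "newman",
        bin_index=bins.bin_index() if bins.B <= stats.K else None,
    )
    return est.normalized()
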