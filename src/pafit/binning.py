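"""Logarithmic degree binning.

To stabilise the estimate, neighbouring degrees can share one parameter:
degree 0 sits in its own bin and degrees ``1..K`` are partitioned into
``B - 1`` intervals whose widths grow geometrically by a common ratio ``c``
(solved from ``B`` and ``K``).  All counts are summed within a bin before
any ratio or likelihood is formed, and the fitted per-bin value is expanded
back to a piecewise-constant kernel over degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse

__all__ = ["BinScheme", "make_bins"]


@dataclass(frozen=True)
class BinScheme:
    """A partition of degrees ``0..K`` into ``B`` contiguous bins.

    ``edges`` has length ``B + 1``: bin ``i`` covers degrees
    ``edges[i] .. edges[i+1] - 1``.
    """

    K: int
    B: int
    edges: np.ndarray
    c: float

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64)
        if e[0] != 0 or e[-1] != self.K + 1 or (np.diff(e) < 1).any():
            raise ValueError("edges must partition 0..K into non-empty bins")
        object.__setattr__(self, "edges", e)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def bin_of(self, k) -> np.ndarray:
        """Bin index for degree(s) ``k``."""
        k = np.asarray(k)
        if (k < 0).any() or (k > self.K).any():
            raise ValueError("degree outside 0..K")
        return np.searchsorted(self.edges, k, side="right") - 1

    def bin_index(self) -> np.ndarray:
        """Bin index of every degree 0..K."""
        return self.bin_of(np.arange(self.K + 1))

    def aggregate(self, rows):
        """Sum an array indexed by degree (axis 0, length K+1) within bins."""
        idx = self.bin_index()
        if sparse.issparse(rows):
            S = sparse.csr_matrix(
                (np.ones(self.K + 1), (idx, np.arange(self.K + 1))),
                shape=(self.B, self.K + 1),
            )
            return S @ rows
        rows = np.asarray(rows)
        out = np.zeros((self.B,) + rows.shape[1:], dtype=rows.dtype)
        np.add.at(out, idx, rows)
        return out

    def expand(self, per_bin: np.ndarray) -> np.ndarray:
        """Piecewise-constant expansion of per-bin values to degrees 0..K."""
        return np.asarray(per_bin)[self.bin_index()]

    def representatives(self) -> np.ndarray:
        """One representative degree per bin (geometric centre, unrounded).

        Degree 0 is clamped to 1 inside the geometric mean, matching the
        ``max(k, 1)`` convention of the standard kernel families.
        """
        lo = self.edges[:-1].astype(float)
        hi = (self.edges[1:] - 1).astype(float)
        rep = np.sqrt(np.maximum(lo, 1.0) * np.maximum(hi, 1.0))
        rep[0] = lo[0]
        return rep


def make_bins(K: int, B: int) -> BinScheme:
    """Build a logarithmic bin scheme over degrees ``0..K``.

    Degree 0 is always its own bin.  Degrees ``1..K`` are split into
    ``B - 1`` intervals whose real-valued widths form a geometric series
    with ratio ``c`` solving ``sum_i c^i = K``, then rounded to integers
    with every bin non-empty.  ``B >= K + 1`` degenerates to one bin per
    degree.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if K < 0:
        raise ValueError("K must be >= 0")
    if K == 0:
        return BinScheme(K=0, B=1, edges=np.array([0, 1]), c=1.0)
    if B == 1:
        return BinScheme(K=K, B=1, edges=np.array([0, K + 1]), c=1.0)

    n_bins = min(B - 1, K)  # bins over 1..K
    if n_bins >= K:
        edges = np.arange(K + 2)
        return BinScheme(K=K, B=K + 1, edges=edges, c=1.0)
    if n_bins == 1:
        return BinScheme(K=K, B=2, edges=np.array([0, 1, K + 1]), c=1.0)

    # solve sum_{i=0}^{n_bins-1} c^i = K for c > 1
    def gap(c):
        return (c**n_bins - 1.0) / (c - 1.0) - K

    # c^(n_bins-1) <= sum of widths = K bounds the ratio from above
    c_hi = K ** (1.0 / (n_bins - 1)) * (1.0 + 1e-9)
    c = optimize.brentq(gap, 1.0 + 1e-12, c_hi)
    w = np.round(c ** np.arange(n_bins)).astype(np.int64)
    w = np.maximum(w, 1)
    diff = K - int(w.sum())
    if diff > 0:
        w[-diff:] += 1
    while diff < 0:
        # shrink the leftmost maximal bin, keeping widths non-decreasing
        i = int(np.argmax(w))
        w[i] -= 1
        diff += 1
    edges = np.concatenate(([0, 1], 1 + np.cumsum(w)))
    return BinScheme(K=K, B=n_bins + 1, edges=edges, c=c)
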