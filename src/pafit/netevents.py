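"""Temporal-network data model and sufficient statistics.

A growing directed network is recorded as a sequence of time-stamped edge
events.  Everything the estimators in this package need is contained in two
families of counts extracted from that event stream: ``n_k(t)``, the number
of existing nodes with in-degree ``k`` at the onset of time-step ``t``, and
``m_k(t)``, the number of new edges arriving at step ``t`` whose target has
onset in-degree ``k``.

Conventions
-----------
* Degrees are **in-degrees** (directed convention; undirected data can be
  symmetrized at read time with ``symmetrize=True``).
* All edges of step ``t`` are scored against *onset* degrees, i.e. the
  degrees computed from edges with time strictly less than ``t``.  This is
  the multinomial sampling model the likelihood assumes: given ``m(t)``
  edges at step ``t``, the counts ``m_0(t), ..., m_K(t)`` are multinomial.
* Nodes whose arrival time equals ``t`` are present (at in-degree 0) in
  ``n_0(t)`` and are eligible targets within step ``t``.
* Edges at ``t = 0`` form the seed network: they contribute to onset
  degrees of step 1 but produce no ``m_k`` counts themselves.
* Time-steps need not be consecutive; a gap is a step with ``m(t) = 0``
  and is simply skipped in all sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "TemporalEdgeList",
    "SuffStats",
    "read_edge_events",
    "write_edge_events",
    "compute_suff_stats",
    "max_in_degree",
]


def max_in_degree(net: "TemporalEdgeList") -> int:
    """Maximum in-degree attained anywhere in the growth process (final net)."""
    counts: dict = {}
    for _, _, v in net.edges:
        counts[v] = counts.get(v, 0) + 1
    return max(counts.values()) if counts else 0


class EdgeEventError(ValueError):
    """Raised for malformed or inconsistent temporal edge data."""


@dataclass(frozen=True)
class TemporalEdgeList:
    """A time-stamped directed edge list with node arrival times.

    Parameters
    ----------
    edges
        Sequence of ``(t, source, target)`` with integer time ``t >= 0``.
    node_arrivals
        Map node id -> time-step of first existence.  If omitted, each
        node's arrival is inferred as its earliest appearance in an edge.
    """

    edges: tuple[tuple[int, object, object], ...]
    node_arrivals: Mapping[object, int]
    T: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.edges:
            raise EdgeEventError("no edges")
        for t, u, v in self.edges:
            if t < 0 or int(t) != t:
                raise EdgeEventError(f"edge time must be a non-negative integer, got {t!r}")
            if u == v:
                raise EdgeEventError(f"self-loop {u!r}->{v!r} at t={t} is not allowed")
            for w in (u, v):
                if w not in self.node_arrivals:
                    raise EdgeEventError(f"node {w!r} missing from node arrivals")
                if self.node_arrivals[w] > t:
                    raise EdgeEventError(
                        f"edge ({t}, {u!r}, {v!r}) references node {w!r} "
                        f"arriving later (t={self.node_arrivals[w]})"
                    )
        object.__setattr__(self, "T", max(t for t, _, _ in self.edges))

    @property
    def n_nodes(self) -> int:
        return len(self.node_arrivals)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_at(self, t: int) -> list:
        """Nodes existing at (the onset of, inclusive of arrivals at) step t."""
        return [v for v, a in self.node_arrivals.items() if a <= t]


def _infer_arrivals(edges: Sequence[tuple[int, object, object]]) -> dict:
    arrivals: dict = {}
    for t, u, v in edges:
        for w in (u, v):
            if w not in arrivals or t < arrivals[w]:
                arrivals[w] = t
    return arrivals


def read_edge_events(
    path: str | Path | IO[str],
    *,
    node_table: str | Path | None = None,
    symmetrize: bool = False,
    comment: str = "#",
) -> TemporalEdgeList:
    """Read a whitespace/TAB-delimited edge-event file.

    Each non-comment line holds ``time source target``.  An optional header
    line is tolerated (detected by a non-integer first field on line 1).
    ``node_table`` optionally names a two-column file ``node arrival_time``
    overriding the inferred arrival times.

    ``symmetrize=True`` duplicates every event with source and target
    swapped, so that undirected data can be analysed under the in-degree
    convention.
    """
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "r")
        close = True
    else:
        fh = path
    edges: list[tuple[int, str, str]] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise EdgeEventError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                t = int(parts[0])
            except ValueError:
                if lineno == 1 and not edges:
                    continue  # header
                raise EdgeEventError(f"line {lineno}: bad time field {parts[0]!r}")
            edges.append((t, parts[1], parts[2]))
            if symmetrize:
                edges.append((t, parts[2], parts[1]))
    finally:
        if close:
            fh.close()
    if not edges:
        raise EdgeEventError("no edges")
    arrivals = _infer_arrivals(edges)
    if node_table is not None:
        with open(node_table, "r") as nf:
            for lineno, line in enumerate(nf, start=1):
                line = line.strip()
                if not line or line.startswith(comment):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise EdgeEventError(
                        f"node table line {lineno}: expected 2 columns, got {len(parts)}"
                    )
                arrivals[parts[0]] = int(parts[1])
    return TemporalEdgeList(edges=tuple(edges), node_arrivals=arrivals)


def write_edge_events(
    net: TemporalEdgeList,
    path: str | Path | IO[str],
    *,
    node_table: str | Path | None = None,
) -> None:
    """Write the edge events (and optionally the node-arrival table) as TSV."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        fh.write("# time\tsource\ttarget\n")
        for t, u, v in net.edges:
            fh.write(f"{t}\t{u}\t{v}\n")
    finally:
        if close:
            fh.close()
    if node_table is not None:
        with open(node_table, "w") as nf:
            nf.write("# node\tarrival\n")
            for v, a in net.node_arrivals.items():
                nf.write(f"{v}\t{a}\n")


@dataclass(frozen=True)
class SuffStats:
    """Sufficient statistics of a growth process.

    ``m_k_t[k, j]`` and ``n_k_t[k, j]`` are indexed by degree ``k`` (rows,
    0..K) and *observed step index* ``j`` (columns); ``times[j]`` gives the
    actual time-step label of column ``j`` (only steps ``t >= 1`` that have
    at least one edge are stored — empty steps contribute nothing to any
    estimator).  ``m_t[j]`` is the number of edges of that step and
    ``N_t[j]`` the number of nodes present at its onset (arrivals at the
    step included).
    """

    m_k_t: sparse.csc_matrix
    n_k_t: sparse.csc_matrix
    m_t: np.ndarray
    N_t: np.ndarray
    times: np.ndarray
    K: int
    T: int

    def validate(self) -> None:
        if not np.array_equal(np.asarray(self.m_k_t.sum(axis=0)).ravel(), self.m_t):
            raise AssertionError("column sums of m_k_t do not match m_t")
        if not np.array_equal(np.asarray(self.n_k_t.sum(axis=0)).ravel(), self.N_t):
            raise AssertionError("column sums of n_k_t do not match N_t")
        if (self.m_k_t.data < 0).any() or (self.n_k_t.data < 0).any():
            raise AssertionError("negative counts")

    @property
    def total_events(self) -> int:
        """Total number of attachment events, sum_t sum_k m_k(t)."""
        return int(self.m_t.sum())

    def m_per_degree(self) -> np.ndarray:
        """sum_t m_k(t) for every degree k = 0..K."""
        return np.asarray(self.m_k_t.sum(axis=1)).ravel()

    def to_frame(self):
        """Long-format table (t, k, m_k, n_k) of the nonzero entries."""
        import pandas as pd

        mc = self.m_k_t.tocoo()
        nc = self.n_k_t.tocoo()
        d: dict[tuple[int, int], list[int]] = {}
        for k, j, v in zip(mc.row, mc.col, mc.data):
            d.setdefault((int(self.times[j]), int(k)), [0, 0])[0] = int(v)
        for k, j, v in zip(nc.row, nc.col, nc.data):
            d.setdefault((int(self.times[j]), int(k)), [0, 0])[1] = int(v)
        rows = [(t, k, mv, nv) for (t, k), (mv, nv) in sorted(d.items())]
        return pd.DataFrame(rows, columns=["t", "k", "m_k", "n_k"])


def compute_suff_stats(net: TemporalEdgeList) -> SuffStats:
    """Extract ``m_k(t)``, ``n_k(t)``, ``m(t)`` and ``N(t)`` from a network.

    Onset-degree convention: every edge of step ``t`` is counted at the
    target's in-degree computed from edges with time ``< t``; degrees are
    not updated within a step.  Nodes arriving at ``t`` enter ``n_0(t)``.
    """
    ids = list(net.node_arrivals.keys())
    index = {v: i for i, v in enumerate(ids)}
    arrivals = np.array([net.node_arrivals[v] for v in ids], dtype=np.int64)
    order = np.argsort(arrivals, kind="stable")

    by_time: dict[int, list[tuple[int, int]]] = {}
    for t, u, v in net.edges:
        by_time.setdefault(t, []).append((index[u], index[v]))

    deg = np.zeros(len(ids), dtype=np.int64)
    for _, tgt in by_time.get(0, []):
        deg[tgt] += 1

    steps = sorted(t for t in by_time if t >= 1)
    rows_m: list[np.ndarray] = []
    cols_m: list[np.ndarray] = []
    vals_m: list[np.ndarray] = []
    rows_n: list[np.ndarray] = []
    cols_n: list[np.ndarray] = []
    vals_n: list[np.ndarray] = []
    m_t = np.zeros(len(steps), dtype=np.int64)
    N_t = np.zeros(len(steps), dtype=np.int64)

    sorted_arrivals = arrivals[order]
    for j, t in enumerate(steps):
        n_present = int(np.searchsorted(sorted_arrivals, t, side="right"))
        present = order[:n_present]
        N_t[j] = n_present
        hist_n = np.bincount(deg[present])
        kk = np.nonzero(hist_n)[0]
        rows_n.append(kk)
        cols_n.append(np.full(kk.size, j))
        vals_n.append(hist_n[kk])

        targets = np.array([tgt for _, tgt in by_time[t]], dtype=np.int64)
        m_t[j] = targets.size
        hist_m = np.bincount(deg[targets])
        kk = np.nonzero(hist_m)[0]
        rows_m.append(kk)
        cols_m.append(np.full(kk.size, j))
        vals_m.append(hist_m[kk])

        np.add.at(deg, targets, 1)

    # K: largest degree with any observed count (the final network's max
    # degree can exceed it but never shows up at a step onset).
    all_rows = rows_m + rows_n
    K = int(max((int(r.max()) for r in all_rows if r.size), default=0))
    shape = (K + 1, len(steps))
    m_k_t = sparse.csc_matrix(
        (np.concatenate(vals_m), (np.concatenate(rows_m), np.concatenate(cols_m))),
        shape=shape,
        dtype=np.int64,
    ) if steps else sparse.csc_matrix(shape, dtype=np.int64)
    n_k_t = sparse.csc_matrix(
        (np.concatenate(vals_n), (np.concatenate(rows_n), np.concatenate(cols_n))),
        shape=shape,
        dtype=np.int64,
    ) if steps else sparse.csc_matrix(shape, dtype=np.int64)

    stats = SuffStats(
        m_k_t=m_k_t,
        n_k_t=n_k_t,
        m_t=m_t,
        N_t=N_t,
        times=np.asarray(steps, dtype=np.int64),
        K=K,
        T=len(steps),
    )
    stats.validate()
    return stats
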