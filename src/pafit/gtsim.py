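"""General temporal (GT) model simulator.

The GT model grows a directed network from a seed: at every time-step ``t``
it adds ``n(t)`` new nodes and ``m(t)`` new edges, each edge choosing its
target ``v`` with probability proportional to the attachment kernel value
``A_k`` at the target's onset in-degree ``k``.  With ``A_k = k^alpha`` this
is Price's model (the directed Barabási–Albert family); with ``A_k = 1`` it
degenerates to an Erdős–Rényi-style random attachment.

Conventions (shared with :mod:`pafit.netevents`):

* targets are drawn i.i.d. within a step against onset degrees — no
  intra-step degree updates, exactly the multinomial sampling model the
  likelihood assumes;
* nodes added at the start of step ``t`` are eligible targets at degree 0;
* each edge's source is drawn uniformly from nodes existing at the onset of
  the step, excluding the chosen target (no self-loops).  Target choice is
  the only degree-dependent part of the model, so the source rule is
  statistically inert for kernel estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .netevents import TemporalEdgeList

__all__ = ["Kernel", "SimConfig", "make_kernel", "simulate_gt"]

#: Degree at which the saturated power family stops growing.
SATURATION_DEGREE = 100


@dataclass(frozen=True)
class Kernel:
    """An attachment kernel ``A_k``: the weight a degree-k node carries.

    ``family`` is one of ``power``, ``saturated_power``, ``log_poly``,
    ``constant`` or ``tabulated``; ``params`` are the family parameters.
    """

    family: str
    params: dict
    _fn: Callable[[np.ndarray], np.ndarray]

    def values(self, k) -> np.ndarray:
        """Kernel value(s) at integer degree(s) ``k >= 0``."""
        k = np.asarray(k)
        if (k < 0).any():
            raise ValueError("degrees must be non-negative")
        return self._fn(k)

    def values_upto(self, K: int) -> np.ndarray:
        """Vector ``[A_0, ..., A_K]``."""
        return self.values(np.arange(K + 1))

    def label(self) -> str:
        ps = ",".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                      for k, v in self.params.items())
        return f"{self.family}({ps})" if ps else self.family


def make_kernel(family: str, **params) -> Kernel:
    """Build one of the standard attachment-kernel families.

    power
        ``A_k = max(k, 1)^alpha`` — the log-linear model; ``alpha = 1`` is
        linear preferential attachment (scale-free regime), ``alpha < 1``
        sub-linear, ``alpha > 1`` super-linear.
    saturated_power
        ``A_k = min(100, max(k, 1))^beta`` — power growth saturating at
        degree 100.
    log_poly
        ``A_k = 3 (log max(k, 1))^b + 1`` — a slowly increasing,
        non-log-linear kernel.
    constant
        ``A_k = 1`` (random attachment).
    tabulated
        ``values=`` a sequence giving ``A_0..A_K``; degrees beyond the
        table raise.
    """
    if family == "power":
        alpha = float(params["alpha"])
        fn = lambda k: np.maximum(k, 1).astype(float) ** alpha
        params = {"alpha": alpha}
    elif family == "saturated_power":
        beta = float(params["beta"])
        sat = int(params.get("saturation", SATURATION_DEGREE))
        if sat < 1:
            raise ValueError("saturation degree must be >= 1")
        fn = lambda k: np.minimum(sat, np.maximum(k, 1)).astype(float) ** beta
        params = {"beta": beta, "saturation": sat}
    elif family == "log_poly":
        b = float(params["b"])
        fn = lambda k: 3.0 * np.log(np.maximum(k, 1)) ** b + 1.0
        params = {"b": b}
    elif family == "constant":
        fn = lambda k: np.ones(np.shape(k), dtype=float)
        params = {}
    elif family == "tabulated":
        table = np.asarray(params["values"], dtype=float)
        if (table < 0).any():
            raise ValueError("tabulated kernel values must be non-negative")

        def fn(k, table=table):
            k = np.asarray(k)
            if (k >= table.size).any():
                raise ValueError("degree beyond tabulated range")
            return table[k]

        params = {"values": tuple(table.tolist())}
    else:
        raise ValueError(f"unknown kernel family {family!r}")
    return Kernel(family=family, params=params, _fn=fn)


@dataclass(frozen=True)
class SimConfig:
    """Growth-schedule configuration for :func:`simulate_gt`.

    Defaults mirror the reference simulation conditions: a 20-node seed,
    ``m(t) = 5`` new edges and ``n(t) = 1`` new node per step, grown until
    2000 nodes.
    """

    seed_nodes: int = 20
    seed_topology: str | Sequence[tuple[int, int]] = "cycle"
    m_per_step: int = 5
    n_per_step: int = 1
    stop_nodes: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_nodes < 1:
            raise ValueError("seed_nodes must be >= 1")
        if self.m_per_step < 1:
            raise ValueError("m_per_step must be >= 1")
        if self.stop_nodes <= self.seed_nodes:
            raise ValueError("stop_nodes must exceed seed_nodes")
        if self.n_per_step < 1:
            raise ValueError("n_per_step must be >= 1")


def _seed_edges(cfg: SimConfig) -> list[tuple[int, int, int]]:
    if isinstance(cfg.seed_topology, str):
        n = cfg.seed_nodes
        if cfg.seed_topology == "cycle":
            if n == 1:
                return []
            return [(0, i, (i + 1) % n) for i in range(n)]
        if cfg.seed_topology == "star":
            return [(0, i, 0) for i in range(1, n)]
        raise ValueError(f"unknown seed topology {cfg.seed_topology!r}")
    return [(0, int(u), int(v)) for u, v in cfg.seed_topology]


def simulate_gt(kernel: Kernel, cfg: SimConfig) -> TemporalEdgeList:
    """Grow one GT-model network and return its edge-event list.

    Node ids are consecutive integers; seed nodes are ``0..seed_nodes-1``
    with arrival 0 and later nodes arrive ``n_per_step`` at a time.  Fully
    reproducible given ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    edges = _seed_edges(cfg)
    arrivals = {i: 0 for i in range(cfg.seed_nodes)}

    # degree array sized for the final node count
    deg = np.zeros(cfg.stop_nodes, dtype=np.int64)
    for _, _, v in edges:
        deg[v] += 1
    n_nodes = cfg.seed_nodes

    t = 0
    while n_nodes < cfg.stop_nodes:
        t += 1
        n_new = min(cfg.n_per_step, cfg.stop_nodes - n_nodes)
        for i in range(n_new):
            arrivals[n_nodes + i] = t
        n_nodes += n_new

        weights = kernel.values(deg[:n_nodes])
        total = weights.sum()
        if not total > 0:
            raise ValueError("kernel gives zero mass to every existing node")
        cum = np.cumsum(weights)
        targets = np.searchsorted(cum, rng.random(cfg.m_per_step) * total, side="right")
        targets = np.minimum(targets, n_nodes - 1)
        for tgt in targets:
            src = int(rng.integers(n_nodes - 1))
            if src >= tgt:
                src += 1  # uniform over existing nodes excluding the target
            edges.append((t, src, int(tgt)))
        np.add.at(deg, targets, 1)

    return TemporalEdgeList(edges=tuple(edges), node_arrivals=arrivals)
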