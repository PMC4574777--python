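import numpy as np
import pytest

from pafit import SimConfig, compute_suff_stats, make_kernel, simulate_gt


@pytest.fixture(scope="session")
def linear_net():
    """A mid-sized linear-preferential-attachment growth process."""
    return simulate_gt(make_kernel("power", alpha=1.0),
                       SimConfig(seed_nodes=20, stop_nodes=800, rng_seed=42))


@pytest.fixture(scope="session")
def linear_stats(linear_net):
    return compute_suff_stats(linear_net)


@pytest.fixture(scope="session")
def toy_net():
    """Small network for dense/brute-force oracles (K and T both tiny)."""
    return simulate_gt(make_kernel("power", alpha=1.0),
                       SimConfig(seed_nodes=8, stop_nodes=14, m_per_step=3, rng_seed=3))


@pytest.fixture(scope="session")
def toy_stats(toy_net):
    return compute_suff_stats(toy_net)


def brute_force_suff_stats(net):
    """Independent oracle: rebuild the network from scratch at every step."""
    times = sorted({t for t, _, _ in net.edges if t >= 1})
    K = 0
    cols = []
    for t in times:
        deg = {v: 0 for v, a in net.node_arrivals.items() if a <= t}
        for s, _, v in net.edges:
            if s < t and v in deg:
                deg[v] += 1
        n_k = {}
        for v, k in deg.items():
            n_k[k] = n_k.get(k, 0) + 1
        m_k = {}
        for s, _, v in net.edges:
            if s == t:
                m_k[deg[v]] = m_k.get(deg[v], 0) + 1
        K = max([K] + list(n_k) + list(m_k))
        cols.append((t, m_k, n_k))
    m_mat = np.zeros((K + 1, len(times)), dtype=np.int64)
    n_mat = np.zeros((K + 1, len(times)), dtype=np.int64)
    for j, (_, m_k, n_k) in enumerate(cols):
        for k, v in m_k.items():
            m_mat[k, j] = v
        for k, v in n_k.items():
            n_mat[k, j] = v
    return np.asarray(times), m_mat, n_mat
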