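import numpy as np
import pytest

from cryosynapse import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """Parallel-plane synapse, 33 nm separation, 2 receptor clusters."""
    return synth.make_synapse_scene(
        extent=400.0, spacing=8.0, n_clusters=2, receptors_per_cluster=8,
        cluster_sigma=15.0, guard_distance=120.0, seed=7)


def brute_force_nn(src: np.ndarray, dst: np.ndarray):
    """Exhaustive nearest-neighbour oracle: all-pairs minimum."""
    d = np.linalg.norm(src[:, None, :] - dst[None, :, :], axis=2)
    return d.min(axis=1), d.argmin(axis=1)


def brute_force_dbscan(D: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN by explicit neighbourhood expansion (oracle)."""
    n = len(D)
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    neigh = [np.nonzero(D[i] <= eps)[0] for i in range(n)]
    cid = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if len(neigh[i]) < min_pts:
            labels[i] = -1
            continue
        cid += 1
        labels[i] = cid
        stack = list(neigh[i])
        while stack:
            j = stack.pop()
            if labels[j] == -1:
                labels[j] = cid
            if labels[j] != -2:
                continue
            labels[j] = cid
            if len(neigh[j]) >= min_pts:
                stack.extend(neigh[j])
    return labels


def floyd_warshall_oracle(n: int, edges, weights) -> np.ndarray:
    """Hand-rolled all-pairs shortest paths (independent of scipy's graph
    routines)."""
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for (i, j), w in zip(edges, weights):
        D[i, j] = min(D[i, j], w)
        D[j, i] = min(D[j, i], w)
    for k in range(n):
        D = np.minimum(D, D[:, k][:, None] + D[k, :][None, :])
    return D


def welch_oracle(a: np.ndarray, b: np.ndarray):
    """Welch t statistic and two-sided p by the textbook formulas."""
    from scipy.stats import t as tdist
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p
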