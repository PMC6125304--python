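import numpy as np
import pytest

from plinet.io_montage import EpochSet, Montage, Recording


@pytest.fixture(scope="session")
def montage():
    return Montage.biosemi64()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """Two channels: 10 Hz cosine and sine (constant pi/2 phase offset)."""
    t = np.arange(4096) / 1024.0
    data = np.vstack([np.cos(2 * np.pi * 10 * t),
                      np.sin(2 * np.pi * 10 * t)])
    return Recording(data=data, rate=1024.0, labels=["a", "b"])


@pytest.fixture
def noise_epochs(rng):
    """White-noise EpochSet: 5 epochs x 3 channels x 4 s at 256 Hz."""
    x = rng.standard_normal((5, 3, 1024))
    return EpochSet(epochs=x, rate=256.0, epoch_length=4.0,
                    labels=["c0", "c1", "c2"])


def chain_matrix(n: int, strong: float = 0.9, weak: float = 0.1):
    """Symmetric PLI matrix whose strongest links form a simple chain."""
    m = np.full((n, n), weak)
    np.fill_diagonal(m, 0.0)
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = strong
    return m


def star_matrix(n: int, strong: float = 0.9, weak: float = 0.1):
    """Symmetric PLI matrix with node 0 strongly linked to every other."""
    m = np.full((n, n), weak)
    np.fill_diagonal(m, 0.0)
    m[0, 1:] = m[1:, 0] = strong
    return m


# ---------------------------------------------------------------------------
# independent brute-force oracles (never call the implementation under test)

def pli_loop_oracle(a, b):
    """Literal loop over the defining sign-average formula."""
    import math
    total = 0.0
    for x, y in zip(a, b):
        s = math.sin(x - y)
        total += (s > 0) - (s < 0)
    return abs(total / len(a))


def min_spanning_tree_oracle(weights):
    """Exhaustive minimum spanning tree by enumerating all edge subsets."""
    import itertools
    n = weights.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best_total, best_edges = np.inf, None
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                acyclic = False
                break
            parent[ri] = rj
        if not acyclic:
            continue
        total = sum(weights[i, j] for i, j in combo)
        if total < best_total:
            best_total, best_edges = total, set(combo)
    return best_total, best_edges


def betweenness_oracle(n, edges):
    """Brute-force path counting in a tree (paths are unique)."""
    adj = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)

    def path(s, t):
        stack, seen = [(s, [s])], {s}
        while stack:
            node, p = stack.pop()
            if node == t:
                return p
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, p + [nb]))
        raise AssertionError("tree is disconnected")

    counts = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            for mid in path(s, t)[1:-1]:
                counts[mid] += 1
    return counts / ((n - 1) * (n - 2) / 2.0)
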