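import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import morphosig as ms


@pytest.fixture
def three_tip_tree() -> ms.TimeTree:
    return ms.TimeTree.from_newick("((A:4,B:4):6,C:10);")


@pytest.fixture
def two_tip_tree() -> ms.TimeTree:
    return ms.TimeTree.from_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def yule64() -> ms.TimeTree:
    return ms.simulate_tree(64, 12345)


@pytest.fixture(scope="session")
def default_fixture() -> ms.SyntheticDataset:
    return ms.make_fixture(seed=7)


def brute_force_loglik(tree: ms.TimeTree, tip_states, Q: np.ndarray,
                       prior=None) -> float:
    """Enumeration oracle: sum over all internal-node state assignments.

    Independent of the pruning implementation; usable for trees with a
    handful of tips only.
    """
    k = Q.shape[0]
    if prior is None:
        prior = np.full(k, 1.0 / k)
    P = {v: expm(Q * tree.edge_length[v])
         for v in range(tree.n_nodes) if v != tree.root}
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tipsets = [range(k) if s < 0 else [int(s)] for s in tip_states]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        for tips in itertools.product(*tipsets):
            for i, s in enumerate(tips):
                amap[i] = s
            p = prior[amap[tree.root]]
            for v in range(tree.n_nodes):
                if v != tree.root:
                    p *= P[v][amap[tree.parent[v]], amap[v]]
            total += p
    return float(np.log(total))


@pytest.fixture
def enumeration_oracle():
    return brute_force_loglik


def kendall_tau_oracle(x, y) -> float:
    """O(n^2) pair enumeration, tau-b tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


@pytest.fixture
def tau_oracle():
    return kendall_tau_oracle
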