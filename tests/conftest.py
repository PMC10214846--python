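import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MM = 1e-3
UL = 1e-9
UL_PER_H = 1e-9 / 3600.0


@pytest.fixture(scope="session")
def ul():
    return UL


@pytest.fixture(scope="session")
def ul_per_h():
    return UL_PER_H


@pytest.fixture(scope="session")
def mm():
    return MM


def dense_solve_oracle(edges, pressures, inflows=None):
    """Independent brute-force nodal solve (dense numpy, direct elimination).

    ``edges``: (a, b, R) triples; ``pressures``: {node: Pa};
    ``inflows``: {node: m^3/s}.  Returns ({node: pressure}, [flow per edge]).
    """
    inflows = inflows or {}
    nodes = sorted({n for e in edges for n in e[:2]}
                   | set(pressures) | set(inflows))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    g = np.zeros((n, n))
    for a, b, r in edges:
        ia, ib = idx[a], idx[b]
        g[ia, ia] += 1.0 / r
        g[ib, ib] += 1.0 / r
        g[ia, ib] -= 1.0 / r
        g[ib, ia] -= 1.0 / r
    rhs = np.zeros(n)
    for node, q in inflows.items():
        rhs[idx[node]] += q
    a_mat = g.copy()
    for node in pressures:
        i = idx[node]
        a_mat[i, :] = 0.0
        a_mat[i, i] = 1.0
    rhs_b = rhs.copy()
    for node, p in pressures.items():
        i = idx[node]
        rhs_b[i] = p
    p_vec = np.linalg.solve(a_mat, rhs_b)
    sol = {node: p_vec[idx[node]] for node in nodes}
    flows = [(sol[a] - sol[b]) / r for a, b, r in edges]
    return sol, flows
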