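"""Minimum dominating sets and the collective-influence-corrected variant.

A dominating set S of an undirected graph G = (V, E) satisfies, for every
node v, the constraint

    x_v + sum_{u in N(v)} x_u >= 1,        x_v in {0, 1},

i.e. every node is a member of S or adjacent to one. The minimum dominating
set (MDS) minimises sum_v x_v; its optimal value is the domination number
gamma(G). Because the optimum is generally non-unique, the CI-MDS model adds
a second stage: among all dominating sets of size exactly gamma(G), maximise
the summed collective influence of the members,

    maximise  sum_v CI_ell(v) * x_v
    s.t.      domination constraints,  sum_v x_v = gamma(G).

Both stages are 0/1 integer programs solved exactly (branch-and-bound with an
optimality proof) through the HiGHS solver behind :func:`scipy.optimize.milp`.
Two interchangeable backends are wired — identical except for the variable
order handed to the solver — so that the solution-stability properties of the
two models can be compared; a brute-force enumeration backend is available
for small graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

from .collective_influence import CIScores, collective_influence
from .errors import EmptyNetworkError, SizeCapError, SolverError, UnknownNodeError
from .graph_core import Network

#: node cap for the exhaustive enumeration oracle (tests only)
ENUMERATION_CAP = 16

BACKENDS = ("highs", "highs-permuted", "enumerate")
_PERMUTATION_SEED = 0xC1  # fixed: the permuted backend must be deterministic


@dataclass(frozen=True)
class DominatingSetResult:
    """An optimal dominating set together with solver provenance.

    ``total_ci`` is 0 for standard-MDS solves and the (exactly optimal)
    summed collective influence of the members for CI-MDS solves.
    """

    members: frozenset[str]
    size: int
    total_ci: int
    backend: str
    status: str = "optimal"


def verify_dominating_set(network: Network, candidate: set[str]) -> bool:
    """True iff every node is in ``candidate`` or adjacent to a member."""
    unknown = set(candidate) - set(network.nodes())
    if unknown:
        raise UnknownNodeError(f"candidate contains unknown node(s): {sorted(unknown)}")
    cand = set(candidate)
    for v in network.nodes():
        if v in cand:
            continue
        if not any(u in cand for u in network[v]):
            return False
    return True


def _node_order(network: Network, backend: str) -> list[str]:
    nodes = sorted(network.nodes())
    if backend == "highs-permuted":
        rng = np.random.default_rng(_PERMUTATION_SEED)
        perm = rng.permutation(len(nodes))
        nodes = [nodes[i] for i in perm]
    return nodes


def _domination_matrix(network: Network, nodes: list[str]) -> sp.csr_array:
    """Row v: x_v + sum_{u in N(v)} x_u (closed-neighbourhood incidence)."""
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for v in nodes:
        i = idx[v]
        rows.append(i)
        cols.append(i)
        for u in network[v]:
            rows.append(i)
            cols.append(idx[u])
    data = np.ones(len(rows))
    n = len(nodes)
    return sp.csr_array((data, (rows, cols)), shape=(n, n))


def _solve_binary_program(c: np.ndarray, constraints: list[LinearConstraint],
                          zero_gap: bool) -> np.ndarray:
    """Solve a 0/1 program exactly.

    With ``zero_gap`` the MIP gap is forced to zero, needed when the exact
    objective value is part of the contract (the CI stage, whose integer
    objective can be large). The cardinality stage keeps the solver's default
    relative gap: for an all-ones objective the certified gap is far below 1,
    so any incumbent within it is provably of minimum cardinality.
    """
    n = len(c)
    options = {"mip_rel_gap": 0.0} if zero_gap else None
    res = milp(c=c, constraints=constraints,
               integrality=np.ones(n), bounds=(0, 1), options=options)
    if not res.success or res.status != 0:
        raise SolverError(f"backend failed to prove optimality: {res.message}")
    gap = getattr(res, "mip_gap", None)
    if not zero_gap and gap is not None and gap * max(1.0, abs(res.fun)) >= 0.5:
        # certified bound too loose to pin the integer optimum — never accept
        raise SolverError(f"optimality certificate too weak (gap {gap})")
    return np.asarray(res.x)


def solve_standard_mds(network: Network, backend: str = "highs") -> DominatingSetResult:
    """Exact minimum-cardinality dominating set (never a heuristic answer)."""
    _check_solvable(network, backend)
    if backend == "enumerate":
        members = enumerate_all_mds(network)[0]
        return DominatingSetResult(frozenset(members), len(members), 0, backend)
    nodes = _node_order(network, backend)
    a = _domination_matrix(network, nodes)
    x = _solve_binary_program(
        np.ones(len(nodes)),
        [LinearConstraint(a, lb=1, ub=np.inf)], zero_gap=False)
    members = frozenset(n for n, xi in zip(nodes, x) if xi > 0.5)
    if not verify_dominating_set(network, set(members)):
        raise SolverError("backend returned a non-dominating set")
    return DominatingSetResult(members, len(members), 0, backend)


def domination_number(network: Network, backend: str = "highs") -> int:
    """gamma(G): size of a minimum dominating set (backend-invariant value)."""
    return solve_standard_mds(network, backend).size


def solve_ci_mds(network: Network, ell: int = 1,
                 backend: str = "highs") -> DominatingSetResult:
    """Two-stage CI-MDS solve.

    Stage 1 computes gamma(G); stage 2 maximises the summed CI_ell over all
    dominating sets of size exactly gamma(G) (hard equality constraint).
    The returned ``total_ci`` is the true maximum over all MDS configurations;
    when several configurations tie on it, membership is backend-dependent.
    """
    _check_solvable(network, backend)
    ci = collective_influence(network, ell)
    gamma = domination_number(network, "highs" if backend == "enumerate" else backend)
    if backend == "enumerate":
        all_mds = enumerate_all_mds(network)
        max_ci = max(ci.total(s) for s in all_mds)
        # canonical tie-break: lexicographically smallest member tuple
        best = min((s for s in all_mds if ci.total(s) == max_ci),
                   key=lambda s: tuple(sorted(s)))
        return DominatingSetResult(frozenset(best), gamma, max_ci, backend)
    nodes = _node_order(network, backend)
    a = _domination_matrix(network, nodes)
    weights = np.array([ci.scores[n] for n in nodes], dtype=float)
    ones = sp.csr_array(np.ones((1, len(nodes))))
    x = _solve_binary_program(
        -weights,  # maximise: exact objective value is part of the contract
        [LinearConstraint(a, lb=1, ub=np.inf),
         LinearConstraint(ones, lb=gamma, ub=gamma)], zero_gap=True)
    members = frozenset(n for n, xi in zip(nodes, x) if xi > 0.5)
    if len(members) != gamma or not verify_dominating_set(network, set(members)):
        raise SolverError("CI-MDS stage-2 solution violates the MDS constraints")
    return DominatingSetResult(members, gamma, int(ci.total(members)), backend)


def enumerate_all_mds(network: Network, cap: int = ENUMERATION_CAP) -> list[frozenset[str]]:
    """All minimum dominating sets, in lexicographic order of member tuples.

    Brute force over subsets by increasing size; intended as a test oracle,
    hence the node cap.
    """
    if network.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot enumerate MDSs of an empty network")
    n = network.number_of_nodes()
    if n > cap:
        raise SizeCapError(f"{n} nodes exceeds the enumeration cap of {cap}")
    nodes = sorted(network.nodes())
    closed = {v: {v} | set(network[v]) for v in nodes}
    for k in range(1, n + 1):
        found = []
        for combo in itertools.combinations(nodes, k):
            covered = set()
            for v in combo:
                covered |= closed[v]
            if len(covered) == n:
                found.append(frozenset(combo))
        if found:
            return found
    raise AssertionError("unreachable: V itself always dominates")


def mds_overlap(set_a: set[str], set_b: set[str]) -> float:
    """Jaccard index |A∩B| / |A∪B| between two dominating sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("overlap of two empty sets is undefined")
    return len(a & b) / len(a | b)


def _check_solvable(network: Network, backend: str) -> None:
    if backend not in BACKENDS:
        from .errors import ConfigurationError
        raise ConfigurationError(
            f"unknown backend {backend!r}; available: {BACKENDS}")
    if network.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot solve an empty network")
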