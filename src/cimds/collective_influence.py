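"""Collective influence centrality.

The collective influence of a node at radius ``ell`` is the product of its
reduced degree (degree minus one) and the sum of reduced degrees of all nodes
at shortest-path distance exactly ``ell``:

    CI_ell(v) = (d_v - 1) * sum_{u at distance ell} (d_u - 1)

At ``ell = 0`` this is the square of the reduced degree. For ``ell`` beyond
the eccentricity of ``v`` the frontier is empty and the score is 0. Scores
are integers throughout, so downstream comparisons are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_core import Network

DEFAULT_ELL = 1


@dataclass(frozen=True)
class CIScores:
    """Collective-influence scores for every node of a network at one radius."""

    ell: int
    scores: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, node: str) -> int:
        return self.scores[node]

    def total(self, members) -> int:
        """Summed score of a node subset (the second-stage objective value)."""
        return sum(self.scores[m] for m in members)


def collective_influence(network: Network, ell: int = DEFAULT_ELL) -> CIScores:
    """Compute CI_ell for every node.

    Isolated nodes (degree 0) score 0: a reduced degree of -1 is meaningless
    and the pipeline only ever solves connected components, so this extension
    is safe. Leaves (degree 1) score 0 at every radius.
    """
    if ell < 0:
        raise ValueError("ell must be non-negative")
    deg = dict(network.degree())
    scores: dict[str, int] = {}
    for v in network.nodes():
        dv = deg[v]
        if dv == 0:
            scores[v] = 0
            continue
        if ell == 0:
            scores[v] = (dv - 1) ** 2
            continue
        if dv == 1:
            scores[v] = 0  # reduced degree zero annihilates the product
            continue
        # single truncated BFS to depth ell; sum reduced degrees on the frontier
        seen = {v}
        frontier = {v}
        for _ in range(ell):
            nxt = set()
            for u in frontier:
                for w in network[u]:
                    if w not in seen:
                        seen.add(w)
                        nxt.add(w)
            frontier = nxt
            if not frontier:
                break
        scores[v] = (dv - 1) * sum(deg[u] - 1 for u in frontier)
    return CIScores(ell=ell, scores=scores)
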