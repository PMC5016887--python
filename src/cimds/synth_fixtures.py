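"""Seeded synthetic-data generators.

These emulate the study inputs at fixture scale: a sparse global interaction
network, a trio of thresholded expression sources whose OR-consolidation
produces the characteristic bimodal expression-breadth profile (about 66 %
of proteins present in nearly all tissues, about 11 % in only 1-3), a small
graph planted with several minimum dominating sets of unequal collective
influence, and per-class attribute values with a controlled location shift.
Every generator is bit-reproducible under a fixed seed and returns its own
ground truth so downstream assertions never have to re-derive it.

What these fixtures do NOT emulate: the scale-free degree structure, the
correlated expression of interacting proteins, and identifier semantics of
a real interactome — conclusions from tests on them are about the
algorithms, not about biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .collective_influence import collective_influence
from .graph_core import Network, make_network
from .mds import enumerate_all_mds
from .tissue_networks import ExpressionTable


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    The breadth mixture defaults (0.659 housekeeping, 0.107 tissue-specific)
    reproduce the reference bimodal profile over 16 tissues; the remainder
    of the mass is spread uniformly over intermediate breadths.
    """

    seed: int = 0
    n_nodes: int = 100
    edge_prob: float = 0.1
    n_tissues: int = 16
    frac_housekeeping: float = 0.659
    frac_tissue_specific: float = 0.107
    source_count: int = 3
    threshold: float = 3.0
    attribute_shift: float = 1.0

    def __post_init__(self):
        if not (0 <= self.frac_housekeeping <= 1 and 0 <= self.frac_tissue_specific <= 1
                and self.frac_housekeeping + self.frac_tissue_specific <= 1):
            raise ValueError("breadth mixture fractions must lie in [0,1] and sum <= 1")
        if self.n_tissues < 1:
            raise ValueError("need at least one tissue")


def random_network(spec: FixtureSpec) -> Network:
    """Seeded Erdős–Rényi graph over labels g0000, g0001, ... (canonical form)."""
    if spec.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 <= spec.edge_prob <= 1.0):
        raise ValueError("edge_prob must be a probability")
    g = nx.gnp_random_graph(spec.n_nodes, spec.edge_prob, seed=spec.seed)
    mapping = {i: f"g{i:04d}" for i in g.nodes()}
    g = nx.relabel_nodes(g, mapping)
    return make_network(g.edges(), singletons=g.nodes())


def preferential_attachment_network(spec: FixtureSpec, m: int = 2) -> Network:
    """Seeded Barabási–Albert graph, for heavier-tailed degree fixtures."""
    g = nx.barabasi_albert_graph(spec.n_nodes, m, seed=spec.seed)
    g = nx.relabel_nodes(g, {i: f"g{i:04d}" for i in g.nodes()})
    return make_network(g.edges(), singletons=g.nodes())


def planted_multi_mds_network(seed: int = 0):
    """A small graph with several MDS configurations of unequal total CI_1.

    The motif: a hub forced into every minimum dominating set by two pendant
    proteins, plus two interchangeable candidate partners c1/c2 that each
    dominate the same satellite proteins — so the minimum dominating sets are
    exactly {hub, c1} and {hub, c2} — with c2 given one extra interaction so
    the two configurations differ in collective influence. The seed varies
    the number of shared satellites. The construction is verified internally
    by exhaustive enumeration before being returned.

    Returns ``(network, all_mds, ci1_scores)`` where ``all_mds`` is the full
    list of minimum dominating sets and ``ci1_scores`` maps node -> CI_1.
    """
    k = seed % 3  # extra shared satellites, keeps the graph at <= 9 nodes
    sats = [f"s{i}" for i in range(1, 3 + k)]
    edges = [("hub", "p1"), ("hub", "p2"), ("hub", "c1"), ("hub", "c2"),
             ("p1", "c2")]
    for s in sats:
        edges += [("c1", s), ("c2", s)]
    g = make_network(edges)
    all_mds = enumerate_all_mds(g)
    ci = collective_influence(g, ell=1)
    totals = sorted(ci.total(s) for s in all_mds)
    assert len(all_mds) >= 2, "construction must admit multiple MDSs"
    assert totals[-1] > totals[-2], "construction must have a unique CI_1 optimum"
    return g, all_mds, dict(ci.scores)


def synthetic_expression(spec: FixtureSpec, network: Network):
    """Per-source expression tables with a planted bimodal breadth profile.

    Each gene draws a breadth: housekeeping (top three tissue counts) with
    probability ``frac_housekeeping``, tissue-specific (1-3 tissues) with
    probability ``frac_tissue_specific``, otherwise an intermediate breadth.
    The gene's expressed tissues are then a random subset of that size, and
    each expressed (gene, tissue) cell exceeds the threshold in at least one
    of the sources (each source independently, so no single source carries
    every call). Returns ``(tables, truth)`` where ``truth`` maps gene ->
    planted breadth, i.e. the breadth the OR-consolidated calls will show.
    """
    rng = np.random.default_rng(spec.seed)
    genes = sorted(network.nodes())
    t = spec.n_tissues
    tissues = [f"tissue{i:02d}" for i in range(1, t + 1)]
    hk_lo = max(t - 2, 1)
    ts_hi = min(3, t)
    mid_lo, mid_hi = ts_hi + 1, hk_lo - 1
    n_genes, n_src = len(genes), spec.source_count
    truth: dict[str, int] = {}
    expressed = np.zeros((n_genes, t), dtype=bool)
    for gi, g in enumerate(genes):
        u = rng.random()
        if u < spec.frac_housekeeping:
            breadth = int(rng.integers(hk_lo, t + 1))
        elif u < spec.frac_housekeeping + spec.frac_tissue_specific:
            breadth = int(rng.integers(1, ts_hi + 1))
        elif mid_lo <= mid_hi:
            breadth = int(rng.integers(mid_lo, mid_hi + 1))
        else:  # degenerate small-T case: bands cover everything
            breadth = int(rng.integers(1, t + 1))
        truth[g] = breadth
        expressed[gi, rng.choice(t, size=breadth, replace=False)] = True
    thr = spec.threshold
    # every cell starts sub-threshold; expressed cells exceed it in a random
    # non-empty subset of the sources (each source independently w.p. 0.6)
    vals = rng.uniform(0.0, thr * 0.8, size=(n_src, n_genes, t))
    above = (rng.random((n_src, n_genes, t)) < 0.6) & expressed
    rescue = expressed & ~above.any(axis=0)
    gi, ti = np.nonzero(rescue)
    above[rng.integers(n_src, size=gi.size), gi, ti] = True
    vals[above] = thr + 0.5 + rng.exponential(2.0, size=int(above.sum()))
    tables = [ExpressionTable(source=f"source{s}",
                              values=pd.DataFrame(vals[s], index=genes,
                                                  columns=tissues),
                              threshold=thr)
              for s in range(n_src)]
    return tables, truth


def planted_class_attributes(classes, attribute_shift: float, seed: int,
                             shifted_labels: tuple[str, ...] = ("HK-MDS", "TS-MDS",
                                                                "Remaining-MDS")):
    """Standard-normal attribute values, shifted up for the designated classes.

    Returns ``(values, truth)`` where ``truth`` maps protein -> applied shift.
    """
    if not classes:
        raise ValueError("classes list is empty")
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    truth: dict[str, float] = {}
    for rec in sorted(classes, key=lambda r: r.protein):
        shift = attribute_shift if rec.label in shifted_labels else 0.0
        values[rec.protein] = float(rng.normal(loc=shift, scale=1.0))
        truth[rec.protein] = shift
    return values, truth
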