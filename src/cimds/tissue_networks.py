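"""Tissue-specific network construction by node removal.

A global binary protein interaction network is reduced to one network per
tissue by keeping only the proteins called expressed in that tissue, so each
tissue network contains only interactions whose two partners are expressed
there simultaneously; the largest connected component of the induced
subgraph is then retained. Expression calls consolidate several measurement
sources (microarray, immunohistochemistry, RNA-seq): a gene counts as
expressed in a tissue if its value exceeds the source's threshold in at
least one source. Thresholds are mandatory per-source configuration — there
are no numeric defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import math

import pandas as pd

from .errors import (ConfigurationError, EmptyNetworkError, UnknownTissueError)
from .graph_core import Network, largest_connected_component

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """One expression source: a gene x tissue numeric table plus its cutoff."""

    source: str
    values: pd.DataFrame  # index: gene symbols, columns: tissue names
    threshold: float

    def __post_init__(self):
        if self.threshold is None or not math.isfinite(self.threshold):
            raise ConfigurationError(
                f"source {self.source!r}: a finite expression threshold is required")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)


def read_expression_table(path: str | Path, source: str,
                          threshold: float) -> ExpressionTable:
    """Read a TSV with genes in the first column and one column per tissue."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(source=source, values=df, threshold=threshold)


@dataclass
class ExpressionCalls:
    """Thresholded OR-consolidation of one or more expression sources."""

    calls: pd.DataFrame  # boolean, index: genes, columns: tissues

    @property
    def tissues(self) -> list[str]:
        return list(self.calls.columns)

    def expressed_genes(self, tissue: str) -> set[str]:
        if tissue not in self.calls.columns:
            raise UnknownTissueError(f"tissue {tissue!r} not in expression calls")
        col = self.calls[tissue]
        return set(col.index[col])


def call_expression(tables: list[ExpressionTable], strict: bool = True) -> ExpressionCalls:
    """Consolidate sources: expressed iff above threshold in >= 1 source.

    ``strict=True`` uses value > threshold ("exceeds"); ``strict=False``
    uses >=. A gene absent from a source contributes False for that source
    (sources may cover different gene universes), never an error.
    """
    if not tables:
        raise ConfigurationError("at least one expression source is required")
    genes = sorted(set().union(*(t.values.index for t in tables)))
    tissues: list[str] = []
    for t in tables:
        for c in t.values.columns:
            if c not in tissues:
                tissues.append(c)
    calls = pd.DataFrame(False, index=genes, columns=tissues)
    for t in tables:
        vals = t.values.reindex(index=genes, columns=tissues)
        above = vals.gt(t.threshold) if strict else vals.ge(t.threshold)
        calls |= above.fillna(False)
    return ExpressionCalls(calls=calls)


@dataclass
class TissueNetworkSet:
    """Per-tissue networks (each already reduced to its LCC)."""

    tissues: list[str]
    networks: dict[str, Network]
    skipped: list[str] = field(default_factory=list)

    def union_nodes(self) -> set[str]:
        out: set[str] = set()
        for net in self.networks.values():
            out |= set(net.nodes())
        return out

    def union_edges(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for net in self.networks.values():
            out |= {(min(u, v), max(u, v)) for u, v in net.edges()}
        return out


def build_tissue_network(global_net: Network, calls: ExpressionCalls,
                         tissue: str) -> Network:
    """Induced subgraph on genes expressed in ``tissue``, then the LCC."""
    expressed = calls.expressed_genes(tissue)
    keep = expressed & set(global_net.nodes())
    induced = global_net.subgraph(keep).copy()
    if induced.number_of_nodes() == 0:
        raise EmptyNetworkError(f"tissue {tissue!r}: no expressed proteins in network")
    return largest_connected_component(induced)


def build_all(global_net: Network, calls: ExpressionCalls) -> TissueNetworkSet:
    """Build every per-tissue network; empty tissues are skipped with a warning."""
    if not calls.tissues:
        raise ConfigurationError("expression calls contain no tissues")
    networks: dict[str, Network] = {}
    skipped: list[str] = []
    for tissue in calls.tissues:
        try:
            net = build_tissue_network(global_net, calls, tissue)
        except EmptyNetworkError:
            logger.warning("tissue %s: empty induced network, skipped", tissue)
            skipped.append(tissue)
            continue
        networks[tissue] = net
        logger.info("tissue %s: %d proteins, %d interactions (post-LCC)",
                    tissue, net.number_of_nodes(), net.number_of_edges())
    return TissueNetworkSet(tissues=[t for t in calls.tissues if t in networks],
                            networks=networks, skipped=skipped)
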