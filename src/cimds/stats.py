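"""Enrichment and distribution-comparison statistics.

Two tools characterise the protein classes: a one-sided Fisher exact test
(hypergeometric upper tail) for enrichment of a class in an annotated gene
set, and the two-sample Kolmogorov-Smirnov test for comparing per-class
attribute distributions (degree, collective influence, betweenness, dN/dS,
PTM counts, ...). Raw p-values are reported; an optional Benjamini-Hochberg
adjustment is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided enrichment of a protein class in an annotation set."""

    in_class_in_set: int
    in_class_total: int
    set_total_in_universe: int
    universe_size: int
    fraction: float
    p_value: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample KS comparison of an attribute between two protein groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float


def fisher_enrichment(class_set: set[str], annotation_set: set[str],
                      universe: set[str]) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test on the 2x2 class/annotation table.

    The p-value is the exact hypergeometric upper-tail probability of drawing
    at least the observed overlap when |class| proteins are sampled without
    replacement from the universe. Members of either set outside the universe
    are dropped with a warning.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    cls = set(class_set) & universe
    ann = set(annotation_set) & universe
    dropped = (len(class_set) - len(cls)) + (len(annotation_set) - len(ann))
    if dropped:
        logger.warning("fisher_enrichment: dropped %d member(s) outside universe",
                       dropped)
    if not cls:
        raise ValueError("class set is empty within the universe")
    k = len(cls & ann)
    m, n_ann, n_cls = len(universe), len(ann), len(cls)
    p = float(sps.hypergeom.sf(k - 1, m, n_ann, n_cls))
    return EnrichmentResult(
        in_class_in_set=k, in_class_total=n_cls,
        set_total_in_universe=n_ann, universe_size=m,
        fraction=k / n_cls, p_value=min(p, 1.0))


def ks_compare(values_a, values_b, group_a: str = "a",
               group_b: str = "b") -> GroupComparison:
    """Two-sample two-sided KS test with the asymptotic p-value."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return GroupComparison(group_a=group_a, group_b=group_b,
                           n_a=int(a.size), n_b=int(b.size),
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue))


def compare_classes(attribute: dict[str, float], classes,
                    pairs: list[tuple[str, str]]) -> list[GroupComparison]:
    """KS-compare an attribute between labelled protein classes.

    ``pairs`` may reference the six class labels or the aggregates ``MDS``
    (n_mds >= 1) and ``NMDS`` (n_mds = 0). Pairs where either group has no
    attribute coverage are skipped with a warning.
    """
    from .classify import ALL_LABELS  # local import: avoid cycle

    known = set(ALL_LABELS) | {"MDS", "NMDS"}
    groups: dict[str, list[float]] = {g: [] for g in known}
    for rec in classes:
        if rec.protein not in attribute:
            continue
        val = attribute[rec.protein]
        groups[rec.label].append(val)
        groups["MDS" if rec.is_mds else "NMDS"].append(val)
    out = []
    for ga, gb in pairs:
        if ga not in known or gb not in known:
            raise ValueError(f"unknown class label in pair ({ga!r}, {gb!r})")
        if not groups[ga] or not groups[gb]:
            logger.warning("compare_classes: skipped (%s, %s) — empty group", ga, gb)
            continue
        out.append(ks_compare(groups[ga], groups[gb], ga, gb))
    return out


def benjamini_hochberg(p_values) -> list[float]:
    """BH-adjusted p-values (optional; raw p-values are the default output)."""
    p = np.asarray(list(p_values), dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj.tolist()


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT-style gene sets: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {p for p in parts[2:] if p}
    return sets
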