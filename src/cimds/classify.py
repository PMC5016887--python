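"""Six-way protein classification by expression and MDS breadth.

Each protein in the union of the tissue networks is characterised by two
counts: ``n_expressed``, the number of tissue networks that contain it
(membership in the post-LCC network operationalises "expressed"), and
``n_mds``, the number of tissues in whose CI-MDS it appears. With T tissues
(T = 16 in the reference setting) and thresholds hk_min = 14, ts_max = 3:

1. HK-MDS: expressed in >= hk_min tissues and an MDS member in >= hk_min.
2. TS-MDS: expressed in <= ts_max tissues and an MDS member in those tissues
   (strict default: n_mds == n_expressed >= 1; a relaxed mode only requires
   n_mds >= 1).
3. Remaining-MDS: any other protein with n_mds >= 1.
4. HK-NMDS: never an MDS member, expressed in >= hk_min tissues.
5. TS-NMDS: never an MDS member, expressed in <= ts_max tissues.
6. Remaining-NMDS: every other protein.

The six labels partition the union protein set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError
from .tissue_networks import TissueNetworkSet

MDS_LABELS = ("HK-MDS", "TS-MDS", "Remaining-MDS")
NMDS_LABELS = ("HK-NMDS", "TS-NMDS", "Remaining-NMDS")
ALL_LABELS = MDS_LABELS + NMDS_LABELS


@dataclass(frozen=True)
class ProteinClassRecord:
    protein: str
    n_expressed: int
    n_mds: int
    label: str

    @property
    def is_mds(self) -> bool:
        return self.n_mds >= 1


def count_breadths(networks: TissueNetworkSet,
                   mds_sets: dict[str, set[str]]) -> dict[str, tuple[int, int]]:
    """Per-protein (n_expressed, n_mds) over the union of tissue networks."""
    for tissue, members in mds_sets.items():
        net = networks.networks.get(tissue)
        if net is None:
            raise ConsistencyError(f"MDS given for unknown tissue {tissue!r}")
        outside = set(members) - set(net.nodes())
        if outside:
            raise ConsistencyError(
                f"tissue {tissue!r}: MDS members outside network: {sorted(outside)[:5]}")
    breadths: dict[str, tuple[int, int]] = {}
    for protein in sorted(networks.union_nodes()):
        n_exp = sum(protein in networks.networks[t] for t in networks.tissues)
        n_mds = sum(protein in mds_sets.get(t, ()) for t in networks.tissues)
        breadths[protein] = (n_exp, n_mds)
    return breadths


def classify_proteins(breadths: dict[str, tuple[int, int]],
                      hk_min: int = 14, ts_max: int = 3,
                      ts_strict: bool = True) -> list[ProteinClassRecord]:
    """Assign one of the six class labels to every protein."""
    if not (hk_min > ts_max >= 1):
        raise ValueError(f"need hk_min > ts_max >= 1, got {hk_min}, {ts_max}")
    records = []
    for protein, (n_exp, n_mds) in sorted(breadths.items()):
        if not (0 <= n_mds <= n_exp):
            raise ConsistencyError(
                f"{protein}: invalid breadths n_mds={n_mds}, n_expressed={n_exp}")
        if n_mds >= 1:
            if n_exp >= hk_min and n_mds >= hk_min:
                label = "HK-MDS"
            elif n_exp <= ts_max and (n_mds == n_exp if ts_strict else True):
                label = "TS-MDS"
            else:
                label = "Remaining-MDS"
        else:
            if n_exp >= hk_min:
                label = "HK-NMDS"
            elif n_exp <= ts_max:
                label = "TS-NMDS"
            else:
                label = "Remaining-NMDS"
        records.append(ProteinClassRecord(protein, n_exp, n_mds, label))
    return records


def class_counts(records: list[ProteinClassRecord]) -> dict[str, int]:
    counts = {label: 0 for label in ALL_LABELS}
    for r in records:
        counts[r.label] += 1
    return counts


def breadth_histogram(breadths: dict[str, tuple[int, int]], field: str,
                      n_tissues: int | None = None) -> dict:
    """Fraction of proteins per tissue-count bin, plus the two band aggregates.

    ``field`` selects expression breadth or MDS breadth. Proteins with a zero
    count for the selected field (e.g. NMDS proteins under ``field='mds'``)
    are excluded: the histogram describes proteins that have the property at
    all, matching how breadth distributions are usually drawn. Bands are
    1..3 (tissue-specific) and T-2..T (housekeeping).
    """
    if not breadths:
        raise ValueError("breadths mapping is empty")
    if field not in ("expressed", "mds"):
        raise ValueError(f"field must be 'expressed' or 'mds', got {field!r}")
    idx = 0 if field == "expressed" else 1
    counts = [b[idx] for b in breadths.values() if b[idx] >= 1]
    if not counts:
        raise ValueError(f"no protein has a nonzero {field} breadth")
    t = n_tissues if n_tissues is not None else max(counts)
    total = len(counts)
    bins = {k: sum(c == k for c in counts) / total for k in range(1, t + 1)}
    low = sum(f for k, f in bins.items() if k <= 3)
    high = sum(f for k, f in bins.items() if k >= t - 2)
    return {"bins": bins, "low_band": low, "high_band": high,
            "n_tissues": t, "n_proteins": total}
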