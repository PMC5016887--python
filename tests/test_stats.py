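import numpy as np
import pytest

from cimds.classify import ProteinClassRecord
from cimds.stats import (benjamini_hochberg, compare_classes, fisher_enrichment,
                         ks_compare, read_gmt)

from oracles import hypergeom_upper_tail, ks_statistic_sweep


class TestFisherEnrichment:
    def test_half_universe_self_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        half = {f"g{i}" for i in range(10)}
        res = fisher_enrichment(half, half, universe)
        assert res.in_class_in_set == 10 and res.fraction == 1.0
        assert res.p_value == pytest.approx(
            hypergeom_upper_tail(10, 20, 10, 10), rel=1e-12)

    def test_disjoint_sets_p_is_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = fisher_enrichment({"g0", "g1"}, {"g5", "g6"}, universe)
        assert res.in_class_in_set == 0
        assert res.p_value == 1.0  # tail from 0 covers everything

    def test_total_overlap_small_class(self):
        universe = {f"g{i}" for i in range(100)}
        cls = {f"g{i}" for i in range(10)}
        res = fisher_enrichment(cls, cls, universe)
        assert res.p_value == pytest.approx(
            hypergeom_upper_tail(10, 100, 10, 10), rel=1e-9)

    def test_matches_brute_force_tail_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            m = int(rng.integers(10, 200))
            universe = {f"g{i}" for i in range(m)}
            n_cls = int(rng.integers(1, m))
            n_ann = int(rng.integers(1, m))
            perm = rng.permutation(m)
            cls = {f"g{i}" for i in perm[:n_cls]}
            ann = {f"g{i}" for i in rng.permutation(m)[:n_ann]}
            res = fisher_enrichment(cls, ann, universe)
            want = hypergeom_upper_tail(res.in_class_in_set, m, n_ann, n_cls)
            assert res.p_value == pytest.approx(want, rel=1e-9)

    def test_monotone_in_overlap_at_fixed_margins(self):
        m, n_cls, n_ann = 60, 15, 20
        tails = [hypergeom_upper_tail(k, m, n_ann, n_cls)
                 for k in range(0, min(n_cls, n_ann) + 1)]
        assert tails == sorted(tails, reverse=True)
        # and the implementation agrees at every achievable overlap
        genes = [f"g{i}" for i in range(m)]
        universe = set(genes)
        ann = set(genes[:n_ann])
        for k in range(0, n_cls + 1):
            cls = set(genes[:k]) | set(genes[n_ann:n_ann + n_cls - k])
            res = fisher_enrichment(cls, ann, universe)
            assert res.p_value == pytest.approx(tails[k], rel=1e-9)

    def test_argument_errors_and_outsider_drop(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"a"}, {"a"}, set())
        with pytest.raises(ValueError):
            fisher_enrichment({"zz"}, {"a"}, {"a", "b"})  # class empty in universe
        res = fisher_enrichment({"a", "zz"}, {"a", "qq"}, {"a", "b"})
        assert res.in_class_total == 1 and res.set_total_in_universe == 1


class TestKsCompare:
    def test_identical_samples(self):
        res = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_disjoint_supports(self):
        res = ks_compare([0, 0, 0], [1, 1, 1])
        assert res.statistic == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])

    def test_matches_ecdf_sweep(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(size=200)
        b = rng.uniform(size=200)
        res = ks_compare(a, b)
        assert res.statistic == pytest.approx(ks_statistic_sweep(a, b), abs=1e-12)


class TestCompareClasses:
    @staticmethod
    def _records():
        recs = []
        for i in range(10):
            recs.append(ProteinClassRecord(f"m{i}", 5, 2, "Remaining-MDS"))
            recs.append(ProteinClassRecord(f"n{i}", 5, 0, "Remaining-NMDS"))
        return recs

    def test_equal_singletons(self):
        recs = [ProteinClassRecord("a", 16, 15, "HK-MDS"),
                ProteinClassRecord("b", 2, 0, "TS-NMDS")]
        out = compare_classes({"a": 1.0, "b": 1.0}, recs, [("HK-MDS", "TS-NMDS")])
        assert out[0].statistic == 0.0

    def test_aggregate_mds_vs_nmds_partition(self):
        recs = self._records()
        attr = {r.protein: float(i) for i, r in enumerate(recs)}
        out = compare_classes(attr, recs, [("MDS", "NMDS")])
        assert out[0].n_a + out[0].n_b == len(recs)

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            compare_classes({"a": 1.0}, self._records(), [("MDS", "bogus")])

    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(0)
        recs = self._records()
        attr = {}
        for r in recs:
            shift = 3.0 if r.label == "Remaining-MDS" else 0.0
            attr[r.protein] = float(rng.normal(shift, 1.0))
        out = compare_classes(attr, recs, [("MDS", "NMDS")])
        assert out[0].statistic > 0.5

    def test_empty_group_skipped(self):
        recs = self._records()
        attr = {r.protein: 1.0 for r in recs if r.label != "Remaining-NMDS"}
        out = compare_classes(attr, recs, [("MDS", "NMDS"),
                                           ("MDS", "Remaining-MDS")])
        assert [c.group_b for c in out] == ["Remaining-MDS"]


def test_benjamini_hochberg_known_example():
    adj = benjamini_hochberg([0.01, 0.04, 0.03, 0.005])
    assert adj == pytest.approx([0.02, 0.04, 0.04, 0.02])


def test_read_gmt(tmp_path):
    f = tmp_path / "sets.gmt"
    f.write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n\n")
    sets = read_gmt(f)
    assert sets == {"setA": {"g1", "g2"}, "setB": {"g3"}}
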