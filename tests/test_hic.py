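import itertools

import numpy as np
import pandas as pd
import pytest

from segcond import (call_ptcs, estimate_cutoff, fallback_score_contacts,
                     load_contact_scores, make_grid, overlap_ptcs,
                     score_segment_pairs)
from segcond.hic import PTC, ContactScoreSet
from segcond.segmentation import Segment


def _seg(sid, chrom, b0, b1, bin_size=5000):
    return Segment(id=sid, chrom=chrom, start=b0 * bin_size, end=b1 * bin_size,
                   mean_pc1=0.0, sd_pc1=0.0, n_bins=b1 - b0,
                   start_bin=b0, end_bin=b1)


def _contacts(rows):
    return ContactScoreSet(pd.DataFrame(
        rows, columns=["chrom1", "pos1", "chrom2", "pos2", "score"]))


def _annot(labels):
    return pd.DataFrame({"segment_id": list(labels),
                         "label": list(labels.values())})


class TestLoadContactScores:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("c1\t100\tc1\t200\t3.5\nc1\t50\tc1\t40\t1.0\nc1\t9\tc2\t9\t2.0\n")
        cs = load_contact_scores(p)
        assert len(cs.records) == 3
        # pos1 > pos2 on the same chromosome is swapped on load
        row = cs.records.iloc[1]
        assert row["pos1"] == 40 and row["pos2"] == 50
        assert cs.n_intra == 2

    def test_header_row_skipped(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("chrom1\tpos1\tchrom2\tpos2\tscore\nc1\t1\tc1\t2\t0.5\n")
        assert len(load_contact_scores(p).records) == 1

    def test_malformed_line_reported(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("c1\t100\tc1\t200\t3.5\nc1\tBAD\tc1\t5\t1.0\n")
        with pytest.raises(ValueError, match="line 2"):
            load_contact_scores(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("")
        assert len(load_contact_scores(p).records) == 0


class TestFallbackScores:
    GRID = make_grid({"c1": 100_000}, 5_000)  # 20 bins

    def test_uniform_contacts_score_zero(self):
        # one pair at every distance-1 bin pair: observed == expected everywhere
        rows = [("c1", b * 5000 + 1, (b + 1) * 5000 + 1) for b in range(19)]
        cs = fallback_score_contacts(pd.DataFrame(rows, columns=["chrom", "pos1", "pos2"]),
                                     self.GRID)
        assert np.allclose(cs.records["score"], 0.0)
        assert cs.source_tag == "fallback"

    def test_eightfold_enrichment_scores_three(self):
        # distance-0 stratum: one bin pair holds 8 contacts, expected mean is
        # 8/20 per possible pair; with alpha ~ 0 the log2 ratio approaches 3
        rows = [("c1", 2, 3)] * 8
        cs = fallback_score_contacts(pd.DataFrame(rows, columns=["chrom", "pos1", "pos2"]),
                                     self.GRID, alpha=1e-9)
        expected = np.log2(8 / (8 / 20))
        assert cs.records["score"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_empty_input(self):
        cs = fallback_score_contacts(pd.DataFrame(columns=["chrom", "pos1", "pos2"]),
                                     self.GRID)
        assert len(cs.records) == 0


class TestScoreSegmentPairs:
    def test_median_pooling_examples(self):
        segs = [_seg("A", "c", 0, 10), _seg("B", "c", 10, 20)]
        rows = [("c", 1000, "c", 51_000, s) for s in (10.0, 20.0, 30.0)]
        rows += [("c", 2000, "c", 3000, 7.0)]
        table = score_segment_pairs(_contacts(rows), segs)
        t = {(r.segment_a, r.segment_b): r for r in table.itertuples(index=False)}
        assert t[("A", "B")].median_score == 20.0  # median of {10,20,30}
        assert t[("A", "B")].n_contacts == 3
        assert t[("A", "A")].median_score == 7.0   # single score -> itself

    def test_median_equals_brute_force_on_random_toys(self):
        rng = np.random.default_rng(0)
        segs = [_seg(f"S{i}", "c", 10 * i, 10 * (i + 1)) for i in range(5)]
        rows, expected = [], {}
        for _ in range(300):
            p1, p2 = sorted(rng.integers(0, 250_000, 2))
            s = float(rng.normal())
            rows.append(("c", p1, "c", p2, s))
            key = tuple(sorted((int(p1 // 50_000), int(p2 // 50_000))))
            expected.setdefault(key, []).append(s)
        table = score_segment_pairs(_contacts(rows), segs, d_max=10**9)
        for r in table.itertuples(index=False):
            key = (int(r.segment_a[1:]), int(r.segment_b[1:]))
            assert r.median_score == pytest.approx(np.median(expected[key]))
        assert len(table) == len(expected)

    def test_distance_cap_excludes_far_pairs(self):
        segs = [_seg("A", "c", 0, 10), _seg("B", "c", 610, 620)]  # 3 Mb apart
        rows = [("c", 1000, "c", 3_051_000, 100.0)] * 5
        table = score_segment_pairs(_contacts(rows), segs, d_max=2_000_000)
        assert len(table) == 0

    def test_contacts_outside_segments_ignored(self):
        segs = [_seg("A", "c", 0, 10)]
        rows = [("c", 1000, "c", 2000, 5.0), ("c", 90_000, "c", 95_000, 9.0)]
        table = score_segment_pairs(_contacts(rows), segs)
        assert len(table) == 1 and table["n_contacts"].iloc[0] == 1


class TestEstimateCutoff:
    GRID = make_grid({"c": 500_000}, 5_000)  # 100 bins

    def _toy(self, rng, true_score=100.0):
        segs = [_seg("A", "c", 10, 20), _seg("B", "c", 30, 40)]
        rows = [("c", 51_000 + i, "c", 151_000 + i, true_score) for i in range(9)]
        # scattered clearly-low background everywhere
        for _ in range(300):
            p1, p2 = sorted(rng.integers(0, 500_000, 2))
            rows.append(("c", p1, "c", p2, float(rng.normal(-3, 0.5))))
        return _contacts(rows), segs

    def test_argmax_separates_true_pairs_from_background(self):
        """The chosen cutoff keeps exactly the high-scoring true pair."""
        rng = np.random.default_rng(1)
        contacts, segs = self._toy(rng)
        c = estimate_cutoff(contacts, segs, self.GRID, n_perm=30, seed=2)
        table = score_segment_pairs(contacts, segs)
        assert c <= 100
        # only the planted pair survives the returned cutoff
        passing = table[table["median_score"] >= c]
        assert len(passing) == 1
        assert {passing["segment_a"].iloc[0], passing["segment_b"].iloc[0]} == {"A", "B"}

    def test_flat_objective_returns_smallest(self):
        segs = [_seg("A", "c", 10, 20), _seg("B", "c", 30, 40)]
        rows = [("c", 51_000, "c", 151_000, 5.0)]
        c = estimate_cutoff(_contacts(rows), segs, self.GRID, n_perm=5,
                            cutoff_grid=np.array([1.0, 2.0, 3.0]), seed=0)
        assert c in (1.0, 2.0, 3.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        contacts, segs = self._toy(rng)
        a = estimate_cutoff(contacts, segs, self.GRID, n_perm=10, seed=5)
        b = estimate_cutoff(contacts, segs, self.GRID, n_perm=10, seed=5)
        assert a == b

    def test_empty_table_rejected(self):
        segs = [_seg("A", "c", 10, 20)]
        with pytest.raises(ValueError, match="empty"):
            estimate_cutoff(_contacts([]), segs, self.GRID, n_perm=2, seed=0)


def _table(rows):
    return pd.DataFrame(rows, columns=["segment_a", "segment_b", "median_score",
                                       "n_contacts", "distance_bp"])


class TestCallPTCs:
    SEGS = [_seg(s, "c", 10 * i, 10 * (i + 1)) for i, s in enumerate("ABCD")]

    def test_transitive_chain_forms_one_ptc(self):
        table = _table([("A", "B", 20.0, 5, 0), ("B", "C", 18.0, 5, 0),
                        ("A", "C", 5.0, 5, 0)])
        annot = _annot({s: "enhancer_enriched" for s in "ABCD"})
        ptcs = call_ptcs(table, annot, self.SEGS, cutoff=17.0)
        assert len(ptcs) == 1
        assert ptcs[0].member_segment_ids == {"A", "B", "C"}

    def test_cutoff_inclusive(self):
        table = _table([("A", "B", 17.0, 1, 0)])
        annot = _annot({"A": "enhancer_enriched", "B": "enhancer_enriched"})
        assert len(call_ptcs(table, annot, self.SEGS, cutoff=17.0)) == 1

    def test_depleted_segment_never_joins(self):
        table = _table([("A", "B", 30.0, 1, 0)])
        annot = _annot({"A": "enhancer_enriched", "B": "enhancer_depleted"})
        assert call_ptcs(table, annot, self.SEGS, cutoff=17.0) == []

    def test_singleton_via_intra_segment_score(self):
        table = _table([("A", "A", 25.0, 3, 0)])
        annot = _annot({"A": "enhancer_enriched"})
        ptcs = call_ptcs(table, annot, self.SEGS, cutoff=17.0)
        assert len(ptcs) == 1 and ptcs[0].member_segment_ids == {"A"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_components(self, seed):
        """Connected components equal an independent transitive-closure oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        segs = [_seg(f"N{i}", "c", 5 * i, 5 * (i + 1)) for i in range(n)]
        annot = _annot({f"N{i}": "enhancer_enriched" for i in range(n)})
        rows = []
        edges = set()
        for i, j in itertools.combinations(range(n), 2):
            score = float(rng.choice([5.0, 25.0]))
            rows.append((f"N{i}", f"N{j}", score, 1, 0))
            if score >= 17.0:
                edges.add((i, j))
        ptcs = call_ptcs(_table(rows), annot, segs, cutoff=17.0)
        # oracle: transitive closure by repeated boolean matrix squaring
        reach = np.eye(n, dtype=bool)
        for i, j in edges:
            reach[i, j] = reach[j, i] = True
        for _ in range(n):
            reach = reach | (reach @ reach)
        nodes = sorted({v for e in edges for v in e})
        oracle = {frozenset(f"N{j}" for j in range(n) if reach[i, j] and j in nodes)
                  for i in nodes}
        assert {p.member_segment_ids for p in ptcs} == oracle

    def test_raising_cutoff_never_merges_or_grows(self):
        rng = np.random.default_rng(9)
        n = 8
        segs = [_seg(f"N{i}", "c", 5 * i, 5 * (i + 1)) for i in range(n)]
        annot = _annot({f"N{i}": "enhancer_enriched" for i in range(n)})
        rows = [(f"N{i}", f"N{j}", float(rng.uniform(0, 40)), 1, 0)
                for i, j in itertools.combinations(range(n), 2)]
        prev_members = None
        for cutoff in [0.0, 10.0, 20.0, 30.0, 41.0]:
            ptcs = call_ptcs(_table(rows), annot, segs, cutoff=cutoff)
            members = sum(len(p.member_segment_ids) for p in ptcs)
            if prev_members is not None:
                assert members <= prev_members
            prev_members = members
        assert prev_members == 0  # above every score


class TestOverlapPTCs:
    def _ptc(self, pid, chrom, s, e):
        return PTC(ptc_id=pid, member_segment_ids=frozenset({pid}), chrom=chrom,
                   span_start=s, span_end=e)

    def test_identical_lists_self_overlap(self):
        a = [self._ptc("p1", "c", 0, 100), self._ptc("p2", "c", 200, 300)]
        assert overlap_ptcs(a, a) == len(a)

    def test_disjoint_chromosomes(self):
        a = [self._ptc("p1", "c1", 0, 100)]
        b = [self._ptc("p2", "c2", 0, 100)]
        assert overlap_ptcs(a, b) == 0

    def test_one_to_many_counts_once(self):
        a = [self._ptc("p1", "c", 0, 1000)]
        b = [self._ptc("q1", "c", 10, 20), self._ptc("q2", "c", 500, 600)]
        assert overlap_ptcs(a, b) == 1
        assert overlap_ptcs(b, a) == 2  # asymmetric by definition
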