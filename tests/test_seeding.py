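"""Greedy srf seeding, expansion mode, full-node seeds, GAF output."""

import random

import pytest

from srfkit import (Anchor, SubPath, build_edge_text_index, full_node_seeds,
                    greedy_srf_seeds, is_srf_seed, revcomp, seeds_to_gaf,
                    spell, top_x_expand)
from srfkit.seeding import AhoCorasick, seed_read


class TestSrfPredicate:
    @pytest.mark.parametrize(
        "sp,expected",
        [
            (SubPath(1, ("v4",), 2), True),    # k=1 full node
            (SubPath(1, ("v4",), 1), False),   # k=1 partial
            (SubPath(2, ("v1", "v3"), 1), False),  # k=2, i>1 and j<||u2||
            (SubPath(1, ("v1", "v3"), 1), True),   # k=2, i=1
            (SubPath(2, ("v1", "v3"), 2), True),   # k=2, j=||u2||
            (SubPath(1, ("v2", "v3", "v4"), 1), True),  # k=3
        ],
    )
    def test_definition(self, g0, sp, expected):
        a = Anchor(1, sum(1 for _ in sp.nodes), sp)  # query interval irrelevant
        assert is_srf_seed(g0, a) is expected


class TestGreedy:
    def test_caggttt_two_seeds(self, g0, g0_index):
        seeds = greedy_srf_seeds(g0, g0_index, "CAGGTTT")
        got = [(s.anchor.query_start, s.anchor.query_end, s.anchor.subpath) for s in seeds]
        assert got == [
            (6, 7, SubPath(1, ("v4",), 2)),
            (1, 5, SubPath(1, ("v2", "v3", "v4"), 1)),
        ]

    def test_full_path_one_seed(self, g0, g0_index):
        seeds = greedy_srf_seeds(g0, g0_index, "ACGGTA")
        assert len(seeds) == 1
        assert (seeds[0].anchor.query_start, seeds[0].anchor.query_end) == (1, 6)

    def test_all_n_no_seeds(self, g0, g0_index):
        assert greedy_srf_seeds(g0, g0_index, "NN") == []

    def test_disjoint_srf_respelling(self, random_iefgs):
        rng = random.Random(31)
        for msa, g in random_iefgs[:8]:
            idx = build_edge_text_index(g)
            s = spell(msa.rows[rng.randrange(msa.m)])
            q = "".join(
                c if rng.random() > 0.05 else rng.choice("ACGT") for c in s
            )
            seeds = greedy_srf_seeds(g, idx, q)
            covered = set()
            for sd in seeds:
                a = sd.anchor
                assert is_srf_seed(g, a)
                assert g.spell(a.subpath) == q[a.query_start - 1 : a.query_end]
                span = set(range(a.query_start, a.query_end + 1))
                assert not span & covered  # pairwise disjoint
                covered |= span

    def test_error_free_read_coverage(self, random_iefgs):
        """Seeds from an error-free row spelling cover >=80% of it."""
        total = covered = 0
        for msa, g in random_iefgs[:8]:
            idx = build_edge_text_index(g)
            q = spell(msa.rows[0])
            seeds = greedy_srf_seeds(g, idx, q)
            total += len(q)
            covered += sum(s.anchor.length for s in seeds)
        assert covered >= 0.8 * total


class TestTopXExpand:
    def test_caggttt_x1_expands_all_occurrences(self, g0, g0_index):
        seeds = top_x_expand(g0, g0_index, "CAGGTTT", 1)
        # the longest greedy match is "CAGGT", which occurs on both
        # v2v3v4 (CAGGTT) and v2v3v5 (CAGGTA)
        assert [(s.anchor.query_start, s.anchor.query_end) for s in seeds] == [(1, 5), (1, 5)]
        assert {s.anchor.subpath.nodes for s in seeds} == {
            ("v2", "v3", "v4"), ("v2", "v3", "v5")
        }

    def test_saturation_superset_of_greedy(self, g0, g0_index):
        q = "CAGGTTT"
        greedy = greedy_srf_seeds(g0, g0_index, q)
        expanded = top_x_expand(g0, g0_index, q, 10)
        greedy_keys = {(s.anchor.query_start, s.anchor.query_end) for s in greedy}
        expanded_keys = {(s.anchor.query_start, s.anchor.query_end) for s in expanded}
        assert greedy_keys <= expanded_keys
        assert len(expanded) >= len(greedy)

    def test_x_zero_rejected(self, g0, g0_index):
        with pytest.raises(ValueError):
            top_x_expand(g0, g0_index, "ACGT", 0)


class TestFullNodeSeeds:
    def test_caggtt(self, g0):
        anchors = full_node_seeds(g0, "CAGGTT")
        got = {(a.query_start, a.query_end, a.subpath.nodes[0]) for a in anchors}
        assert got == {(1, 2, "v2"), (3, 4, "v3"), (5, 6, "v4")}

    def test_overlapping_occurrences(self, g0):
        anchors = full_node_seeds(g0, "GGGG")
        assert [(a.query_start, a.query_end) for a in anchors] == [(1, 2), (2, 3), (3, 4)]

    def test_empty_query(self, g0):
        assert full_node_seeds(g0, "") == []

    def test_equals_naive_scan(self, random_iefgs):
        rng = random.Random(17)
        for msa, g in random_iefgs[:8]:
            q = spell(msa.rows[0])[:40]
            got = {
                (a.query_start, a.query_end, a.subpath.nodes[0])
                for a in full_node_seeds(g, q)
            }
            naive = set()
            for v in g.nodes():
                lab = g.labels[v]
                for x in range(len(q) - len(lab) + 1):
                    if q[x : x + len(lab)] == lab:
                        naive.add((x + 1, x + len(lab), v))
            assert got == naive

    def test_aho_corasick_overlapping_patterns(self):
        ac = AhoCorasick(["AB", "BAB", "B"])
        hits = sorted(ac.finditer("ABAB"))
        assert (2, "AB") in hits and (4, "BAB") in hits and (2, "B") in hits


class TestStrandsAndGaf:
    def test_gaf_line_fixture(self, g0):
        from srfkit.seeding import Seed
        seed = Seed("r1", Anchor(1, 5, SubPath(1, ("v2", "v3", "v4"), 1)))
        line = seeds_to_gaf([seed], g0, {"r1": 7})[0]
        assert line == "r1\t7\t0\t5\t+\t>v2>v3>v4\t6\t0\t5\t5\t5\t255"

    def test_empty_seed_list(self, g0):
        assert seeds_to_gaf([], g0, {}) == []

    def test_minus_strand_coordinates_on_original_read(self, g0, g0_index):
        read = revcomp("CAGGTT")  # read is the '-' strand of a path
        seeds = seed_read(g0, g0_index, "r", read)
        minus = [s for s in seeds if s.strand == "-"]
        assert minus
        best = max(minus, key=lambda s: s.length)
        assert (best.anchor.query_start, best.anchor.query_end) == (1, 6)
        # subpath stays on the forward graph
        assert g0.spell(best.anchor.subpath) == "CAGGTT"

    def test_forward_only_flag(self, g0, g0_index):
        seeds = seed_read(g0, g0_index, "r", "ACGGTA", both_strands=False)
        assert all(s.strand == "+" for s in seeds)
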