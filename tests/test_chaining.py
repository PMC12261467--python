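"""EDS chaining: precedence, connect cost, DP vs iterative solver,
and the anchored-edit-distance equivalence on degenerate instances."""

import random

import edlib
import pytest

from srfkit import (Anchor, ChainConfig, EDS, SubPath, anchored_edit_distance,
                    chain_chainx, chain_dp, common_substring_anchors,
                    connect_cost, precedes, split_to_node_anchors)
from srfkit.chaining import BlockTables, chain_implied_subpath, eds_spell


def A(x, y, i, nodes, j, strand="+"):
    return Anchor(x, y, SubPath(i, tuple(nodes), j), strand)


@pytest.fixture(scope="module")
def t0(request):
    g0 = request.getfixturevalue("g0")
    return BlockTables.from_graph(g0)


class TestSplit:
    def test_three_node_split(self, g0):
        parts = split_to_node_anchors(g0, A(1, 5, 1, ["v2", "v3", "v4"], 1))
        assert [(p.query_start, p.query_end, p.subpath) for p in parts] == [
            (1, 2, SubPath(1, ("v2",), 2)),
            (3, 4, SubPath(1, ("v3",), 2)),
            (5, 5, SubPath(1, ("v4",), 1)),
        ]

    def test_node_anchor_identity(self, g0):
        a = A(2, 3, 1, ["v3"], 2)
        assert split_to_node_anchors(g0, a) == [a]

    def test_split_respell(self, g0):
        a = A(2, 3, 2, ["v1", "v3"], 1)
        parts = split_to_node_anchors(g0, a)
        spelled = "".join(
            g0.labels[p.subpath.nodes[0]][p.subpath.start_offset - 1 : p.subpath.end_offset]
            for p in parts
        )
        assert spelled == g0.spell(a.subpath)

    def test_inconsistent_interval_rejected(self, g0):
        with pytest.raises(ValueError):
            split_to_node_anchors(g0, A(2, 4, 2, ["v1", "v3"], 1))


class TestPrecedes:
    def test_block_order(self, t0):
        assert precedes(A(3, 4, 1, ["v3"], 2), A(5, 5, 1, ["v4"], 1), t0)

    def test_same_node_offset_order(self, t0):
        assert precedes(A(5, 5, 1, ["v4"], 1), A(6, 7, 1, ["v4"], 2), t0)

    def test_query_order_violation(self, t0):
        assert not precedes(A(5, 5, 1, ["v4"], 1), A(3, 4, 1, ["v3"], 2), t0)

    def test_same_block_different_nodes_never_precede(self, t0):
        assert not precedes(A(1, 2, 1, ["v4"], 2), A(3, 4, 1, ["v5"], 2), t0)


class TestConnectCost:
    def test_adjacent_blocks_zero(self, t0):
        assert connect_cost(A(3, 4, 1, ["v3"], 2), A(5, 5, 1, ["v4"], 1), t0) == 0

    def test_skipped_block_charges_min_length(self, t0):
        # graph gap crosses block 2 (min length 2), query adjacent
        assert connect_cost(A(1, 2, 1, ["v1"], 2), A(3, 3, 1, ["v4"], 1), t0) == 2

    def test_same_node_overlap_difference(self, t0):
        assert connect_cost(A(5, 5, 1, ["v4"], 1), A(6, 7, 1, ["v4"], 2), t0) == 1

    def test_non_preceding_pair_rejected(self, t0):
        with pytest.raises(ValueError):
            connect_cost(A(5, 5, 1, ["v4"], 1), A(3, 4, 1, ["v3"], 2), t0)

    def test_nonnegative_on_random_pairs(self, t0):
        rng = random.Random(3)
        nodes = {"v1": 2, "v2": 2, "v3": 2, "v4": 2, "v5": 2}
        anchors = []
        for _ in range(60):
            v = rng.choice(list(nodes))
            i = rng.randint(1, 2)
            j = rng.randint(i, 2)
            x = rng.randint(1, 15)
            anchors.append(A(x, x + (j - i), i, [v], j))
        for ap in anchors:
            for aq in anchors:
                if ap is not aq and precedes(ap, aq, t0):
                    assert connect_cost(ap, aq, t0) >= 0


class TestChainDP:
    def test_caggttt_instance_opt_one(self, g0, t0):
        seeds = [A(1, 5, 1, ["v2", "v3", "v4"], 1), A(6, 7, 1, ["v4"], 2)]
        anchors = [p for s in seeds for p in split_to_node_anchors(g0, s)]
        res = chain_dp(anchors, t0, 7, ChainConfig(mode="global"))
        assert res.cost == 1
        # equals the read's true edit distance to its best path spelling
        assert edlib.align("CAGGTTT", "CAGGTT", task="distance")["editDistance"] == 1

    def test_single_full_cover_costs_zero(self, g0, t0):
        anchors = split_to_node_anchors(g0, A(1, 6, 1, ["v2", "v3", "v4"], 2))
        assert chain_dp(anchors, t0, 6, ChainConfig(mode="global")).cost == 0

    def test_empty_anchor_set_terminal_gap(self):
        # |Q|=5 against an EDS of shortest path length 4
        eds = EDS([["a"], ["b"]], {"a": "AC", "b": "GT"})
        t = BlockTables.from_graph(eds)
        assert chain_dp([], t, 5, ChainConfig(mode="global")).cost == 5
        assert chain_dp([], t, 5, ChainConfig(mode="semiglobal")).cost == 5


def _random_instance(rng, overlapping=False):
    b = rng.randint(2, 8)
    blocks, labels = [], {}
    nid = 0
    for _ in range(b):
        blk = []
        for _ in range(rng.randint(1, 3)):
            nid += 1
            v = f"u{nid}"
            labels[v] = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            blk.append(v)
        blocks.append(blk)
    t = BlockTables.from_graph(EDS(blocks, labels))
    qlen = rng.randint(10, 40)
    anchors, pos = [], 1
    while pos <= qlen and len(anchors) < 14:
        L = rng.randint(1, 3)
        if pos + L - 1 > qlen:
            break
        if rng.random() < 0.75:
            v = rng.choice([v for blk in blocks for v in blk])
            if len(labels[v]) >= L:
                i = rng.randint(1, len(labels[v]) - L + 1)
                anchors.append(A(pos, pos + L - 1, i, [v], i + L - 1))
        pos += (0 if overlapping and rng.random() < 0.4 else L) + rng.randint(0, 3)
    return t, qlen, anchors


class TestChainX:
    def test_fixture_equals_dp(self, g0, t0):
        seeds = [A(1, 5, 1, ["v2", "v3", "v4"], 1), A(6, 7, 1, ["v4"], 2)]
        anchors = [p for s in seeds for p in split_to_node_anchors(g0, s)]
        cfg = ChainConfig(mode="global")
        assert chain_chainx(anchors, t0, 7, cfg).cost == chain_dp(anchors, t0, 7, cfg).cost == 1

    def test_error_free_tiling_zero_first_iteration(self, g0, t0):
        anchors = split_to_node_anchors(g0, A(1, 6, 1, ["v2", "v3", "v4"], 2))
        res = chain_chainx(anchors, t0, 6, ChainConfig(mode="global", b1=1))
        assert res.cost == 0
        assert res.iterations == 1

    def test_equals_dp_on_nonoverlapping_instances(self):
        rng = random.Random(404)
        for _ in range(120):
            t, qlen, anchors = _random_instance(rng)
            for mode in ("global", "semiglobal"):
                cfg = ChainConfig(mode=mode, b1=rng.choice([1, 4, 64]),
                                  alpha=rng.choice([2.0, 4.0]))
                d = chain_dp(anchors, t, qlen, cfg)
                x = chain_chainx(anchors, t, qlen, cfg)
                assert x.cost == d.cost

    def test_never_below_dp_even_with_overlaps(self):
        rng = random.Random(505)
        for _ in range(60):
            t, qlen, anchors = _random_instance(rng, overlapping=True)
            cfg = ChainConfig(mode="global", b1=2, alpha=2.0)
            assert chain_chainx(anchors, t, qlen, cfg).cost >= chain_dp(anchors, t, qlen, cfg).cost

    def test_beta_guess_path(self):
        rng = random.Random(606)
        t, qlen, anchors = _random_instance(rng)
        cfg = ChainConfig(mode="global", beta=0.5)
        assert chain_chainx(anchors, t, qlen, cfg).cost == chain_dp(anchors, t, qlen, cfg).cost

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ChainConfig(alpha=1.0)
        with pytest.raises(ValueError):
            ChainConfig(mode="local")


class TestAnchoredEditDistanceEquivalence:
    @staticmethod
    def degenerate_instance(t1, t2):
        blocks = [[f"n{j}"] for j in range(len(t2))]
        labels = {f"n{j}": t2[j] for j in range(len(t2))}
        t = BlockTables.from_graph(EDS(blocks, labels))
        node_anchors = []
        for (x, y), (a, b) in common_substring_anchors(t1, t2):
            for k in range(y - x + 1):
                node_anchors.append(A(x + k, x + k, 1, [f"n{a + k - 1}"], 1))
        return t, node_anchors

    def test_identical_strings_cost_zero(self):
        t, anchors = self.degenerate_instance("ACGT", "ACGT")
        assert chain_dp(anchors, t, 4, ChainConfig(mode="global")).cost == 0
        assert anchored_edit_distance("ACGT", "ACGT", [((1, 4), (1, 4))]) == 0

    def test_explicit_anchor_example(self):
        anchors = [((1, 1), (1, 1)), ((3, 4), (2, 3))]
        assert anchored_edit_distance("ACGT", "AGT", anchors) == 1

    def test_no_anchor_cost_is_substitution_bounded(self):
        # without anchors only indels/substitutions remain
        assert anchored_edit_distance("AAAA", "CC", []) == 4

    def test_chain_cost_equals_anchored_distance_random(self):
        rng = random.Random(808)
        for _ in range(80):
            t1 = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            t2 = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            t, anchors = self.degenerate_instance(t1, t2)
            cost = chain_dp(anchors, t, len(t1), ChainConfig(mode="global")).cost
            aed = anchored_edit_distance(t1, t2, common_substring_anchors(t1, t2))
            assert cost == aed
            assert aed == edlib.align(t1, t2, task="distance")["editDistance"]


class TestImpliedSubpath:
    def test_bridges_skipped_blocks(self, g0, t0):
        chain = [A(1, 2, 1, ["v1"], 2), A(3, 3, 1, ["v4"], 1)]
        sp = chain_implied_subpath(chain, t0)
        assert sp.nodes == ("v1", "v3", "v4")
        assert eds_spell(t0, sp) == "ACGGT"

    def test_flank_extension_covers_query(self, g0, t0):
        chain = [A(3, 4, 1, ["v3"], 2)]
        sp = chain_implied_subpath(chain, t0, qlen=6)
        spelled = eds_spell(t0, sp)
        assert len(spelled) == 6
        assert sp.nodes[1] == "v3"

    def test_empty_chain(self, t0):
        assert chain_implied_subpath([], t0) is None
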