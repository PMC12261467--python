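"""MSA segmentation: validity, f values, the DP, construction, repair."""

import itertools

import pytest

from srfkit import (MSA, Segmentation, build_efg, check_semi_repeat_free,
                    compute_f_approx, compute_f_exact, is_valid_segment,
                    optimal_segmentation, repair_segmentation, segment_msa,
                    spell, validate_efg)
from srfkit.matching import brute_force_match
from srfkit.msa import INF, SegmentationError

from conftest import make_random_iefg


@pytest.mark.parametrize(
    "row,expected",
    [("A-C-", "AC"), ("----", ""), ("ACGT", "ACGT")],
)
def test_spell(row, expected):
    assert spell(row) == expected


class TestSegmentValidity:
    @pytest.mark.parametrize(
        "x,y,valid",
        [(2, 2, False), (2, 3, True), (1, 4, True), (1, 1, True)],
    )
    def test_m0_segments(self, m0, x, y, valid):
        assert is_valid_segment(m0, x, y) is valid

    def test_bounds_checked(self, m0):
        with pytest.raises(ValueError):
            is_valid_segment(m0, 3, 2)


class TestFValues:
    def test_m0_exact(self, m0):
        assert compute_f_exact(m0) == [1, 3, 3, INF]

    def test_single_row_all_distinct_symbols(self):
        assert compute_f_exact(MSA(["ACGT"])) == [1, 2, 3, 4]

    def test_identical_rows_collapse(self):
        assert compute_f_exact(MSA(["AC", "AC"])) == [1, 2]

    def test_f_is_minimal(self, m0):
        # every f[j] is the smallest valid right end (brute recheck)
        f = compute_f_exact(m0)
        for j in range(1, m0.n + 1):
            for y in range(j, m0.n + 1):
                first_valid = is_valid_segment(m0, j, y)
                if first_valid:
                    assert f[j - 1] == y
                    break
            else:
                assert f[j - 1] == INF

    def test_approx_k1_equals_exact(self, m0):
        assert compute_f_approx(m0, 1) == compute_f_exact(m0)

    def test_approx_km_is_elementwise_max_of_rows(self, m0):
        # oracle: per-row f values maxed
        per_row = [compute_f_exact(MSA([r])) for r in m0.rows]
        expect = [max(vals) for vals in zip(*per_row)]
        assert compute_f_approx(m0, m0.m, seed=0) == expect

    def test_approx_deterministic_under_seed(self):
        msa = MSA(["ACGT-A", "A-GTCA", "ACGTCA"])
        a = compute_f_approx(msa, 2, seed=9)
        b = compute_f_approx(msa, 2, seed=9)
        assert a == b

    def test_approx_k_out_of_range(self, m0):
        with pytest.raises(ValueError):
            compute_f_approx(m0, m0.m + 1)


def _enumerate_segmentations(msa):
    """All partitions of [1..n] into brute-force-valid segments."""
    n = msa.n
    results = []
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        segs = [(bounds[k] + 1, bounds[k + 1]) for k in range(len(bounds) - 1)]
        if all(is_valid_segment(msa, x, y) for x, y in segs):
            results.append(tuple(segs))
    return results


class TestOptimalSegmentation:
    def test_m0_minmax_height(self, m0):
        f = compute_f_exact(m0)
        seg = optimal_segmentation(f, m0.n, msa=m0)
        # oracle: exhaustive enumeration under the same objective order
        def height(x, y):
            return len({spell(r[x - 1 : y]) for r in m0.rows})
        cands = _enumerate_segmentations(m0)
        best = min(
            cands,
            key=lambda segs: (
                max(height(x, y) for x, y in segs),
                -len(segs),
                tuple(y for _, y in segs),
            ),
        )
        assert seg.segments == best == ((1, 1), (2, 4))

    def test_single_column(self):
        assert optimal_segmentation([1], 1, objective="maxblocks").segments == ((1, 1),)

    def test_unstartable_column_one_errors(self):
        with pytest.raises(SegmentationError):
            optimal_segmentation([INF, INF], 2, objective="maxblocks")

    def test_matches_enumeration_on_random_instances(self):
        from srfkit import random_msa
        for s in range(10):
            msa = random_msa(3, 8, 0.1, 0.1, seed=300 + s)
            f = compute_f_exact(msa)
            def height(x, y):
                return len({spell(r[x - 1 : y]) for r in msa.rows})
            cands = _enumerate_segmentations(msa)
            if not cands:
                with pytest.raises(SegmentationError):
                    optimal_segmentation(f, msa.n, msa=msa)
                continue
            best = min(
                cands,
                key=lambda segs: (
                    max(height(x, y) for x, y in segs),
                    -len(segs),
                    tuple(y for _, y in segs),
                ),
            )
            assert optimal_segmentation(f, msa.n, msa=msa).segments == best


class TestBuildEfg:
    def test_m0_two_blocks(self, m0):
        g = build_efg(m0, Segmentation(((1, 1), (2, 4))))
        assert sorted(g.labels.values()) == ["A", "CGT", "TGT"]
        assert len(g.edges) == 2
        assert check_semi_repeat_free(g) == []

    def test_m0_single_block(self, m0):
        g = build_efg(m0, Segmentation(((1, 4),)))
        assert len(g.labels) == 2 and not g.edges

    def test_empty_spell_rejected(self):
        msa = MSA(["A-", "AC"])
        with pytest.raises(ValueError, match="empty label"):
            build_efg(msa, Segmentation(((1, 1), (2, 2))))


class TestRepair:
    def test_valid_segmentation_is_fixed_point(self, m0):
        seg = Segmentation(((1, 1), (2, 4)))
        assert repair_segmentation(m0, seg).segments == seg.segments

    def test_invalid_blocks_merge(self):
        # [1..1] of {"T","T"} recurs inside rows -> must merge
        msa = MSA(["TAGT", "TCGT"])
        seg = repair_segmentation(msa, Segmentation(((1, 1), (2, 4))))
        g = build_efg(msa, seg)
        assert check_semi_repeat_free(g) == []

    def test_approx_pipeline_always_validates(self):
        from srfkit import random_msa
        for s in range(15):
            msa = random_msa(5, 30, 0.05, 0.1, seed=700 + s)
            _, g = segment_msa(msa, approx_k=3, seed=s)
            assert validate_efg(g).is_iefg


class TestPipelineProperties:
    def test_every_row_spelled_by_some_path(self, random_iefgs):
        for msa, g in random_iefgs:
            for row in msa.rows:
                res, _ = brute_force_match(g, spell(row))
                assert res.found

    def test_exact_pipeline_validates(self, random_iefgs):
        for _, g in random_iefgs[:8]:
            assert validate_efg(g).is_iefg
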