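import random

import pytest

from srfkit import EFGraph, MSA, build_edge_text_index, random_msa, segment_msa


@pytest.fixture(scope="session")
def g0() -> EFGraph:
    """Three-block fixture graph with path spellings ACGGTT, ACGGTA,
    CAGGTT, CAGGTA."""
    return EFGraph(
        [["v1", "v2"], ["v3"], ["v4", "v5"]],
        {"v1": "AC", "v2": "CA", "v3": "GG", "v4": "TT", "v5": "TA"},
        [("v1", "v3"), ("v2", "v3"), ("v3", "v4"), ("v3", "v5")],
    )


@pytest.fixture(scope="session")
def g0_index(g0):
    return build_edge_text_index(g0)


@pytest.fixture(scope="session")
def m0() -> MSA:
    return MSA(["ACGT", "ATGT"])


def make_random_iefg(seed: int, max_m: int = 6, max_n: int = 40):
    """Random MSA -> exact-f pipeline -> (msa, graph)."""
    rng = random.Random(seed)
    m = rng.randint(2, max_m)
    n = rng.randint(10, max_n)
    msa = random_msa(m, n, 0.05, 0.1, seed=seed)
    _, g = segment_msa(msa)
    return msa, g


@pytest.fixture(scope="session")
def random_iefgs():
    """A small shared pool of pipeline-built graphs with their MSAs."""
    return [make_random_iefg(1000 + s) for s in range(20)]
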