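import pytest

from netquery import Network, QueryTree, ScoringParams, SimilarityMatrix


@pytest.fixture
def params():
    """One-indel scoring parameters used throughout the small-instance tests."""
    return ScoringParams(max_ins=1, max_del=1)


@pytest.fixture
def path_query():
    """3-node path query a-b-c."""
    return QueryTree("q", ["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])


@pytest.fixture
def path_target():
    """4-node path target x-y-z-w with unit weights."""
    return Network(
        "t", ["x", "y", "z", "w"], [("x", "y", 1.0), ("y", "z", 1.0), ("z", "w", 1.0)]
    )


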