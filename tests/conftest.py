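import numpy as np
import pandas as pd
import pytest

from locustexpr.catalog import ClusterMap, TranscriptCatalog
from locustexpr.readcount import CountTable
from locustexpr.seqcluster import MatchRecord


@pytest.fixture
def small_catalog() -> TranscriptCatalog:
    return TranscriptCatalog(
        lengths=pd.Series({"A": 900, "B": 1200, "C": 700, "D": 500, "E": 2000})
    )


@pytest.fixture
def chain_matches() -> list[MatchRecord]:
    # A-B and B-C pass the expression preset; D, E stay singletons
    return [
        MatchRecord("A", "B", 800, 0.99),
        MatchRecord("B", "C", 650, 0.98),
    ]


@pytest.fixture
def abc_clusters(small_catalog, chain_matches) -> ClusterMap:
    from locustexpr.seqcluster import build_clusters

    return build_clusters(chain_matches, small_catalog)


@pytest.fixture
def pair_counts() -> CountTable:
    counts = pd.DataFrame(
        {"lib1": [10, 0, 50, 3], "lib2": [5, 7, 50, 0]},
        index=["u1", "u2", "u3", "u4"],
    )
    return CountTable(counts, totals=counts.sum(axis=0))
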