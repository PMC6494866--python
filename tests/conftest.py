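import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microdys.tables_io import CountTable
from microdys.synthetic_cohort import CohortSpec, generate_cohort

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree() -> TreeNode:
    return TreeNode.read(io.StringIO(TOY_NEWICK))


@pytest.fixture
def small_table() -> CountTable:
    counts = pd.DataFrame(
        {"s1": [6, 4, 0], "s2": [2, 8, 0], "s3": [0, 0, 10]},
        index=["A", "B", "C"],
    )
    return CountTable(counts)


@pytest.fixture
def taxonomy_table() -> CountTable:
    counts = pd.DataFrame(
        {"s1": [3, 5, 2, 1], "s2": [0, 7, 1, 4]},
        index=["o1", "o2", "o3", "o4"],
    )
    taxonomy = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 4,
            "phylum": ["p1", "p1", "p2", "p2"],
            "genus": ["g1", "g1", "g2", np.nan],
        },
        index=counts.index,
    )
    return CountTable(counts, taxonomy)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed fixed)."""
    return generate_cohort(CohortSpec(seed=11))
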