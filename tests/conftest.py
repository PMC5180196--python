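import zlib

import numpy as np
import pandas as pd
import pytest

from metacomm.io_formats import (
    DEFAULT_ENV_VARIABLES,
    OtuTable,
    PhyloTree,
    SampleMetadata,
)

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def toy_tree() -> PhyloTree:
    return PhyloTree.from_newick(TOY_NEWICK)


@pytest.fixture
def toy_otu_table() -> OtuTable:
    counts = np.array([
        [10, 0, 5, 1],
        [0, 20, 5, 0],
        [3, 3, 3, 3],
    ])
    taxonomy = {
        "A": "Bacteria;Cyanobacteria",
        "B": "Bacteria;Cyanobacteria",
        "C": "Bacteria;Proteobacteria;Alphaproteobacteria",
        "D": "Unclassified",
    }
    return OtuTable(["s1", "s2", "s3"], ["A", "B", "C", "D"], counts, taxonomy)


def make_metadata(
    sample_ids,
    months=None,
    latitudes=None,
    longitudes=None,
    env=None,
    env_variables=DEFAULT_ENV_VARIABLES,
) -> SampleMetadata:
    n = len(sample_ids)
    rng = np.random.default_rng(zlib.crc32("|".join(map(str, sample_ids)).encode()))
    df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    df["month"] = months if months is not None else ["April"] * n
    df["latitude"] = latitudes if latitudes is not None else np.linspace(56, 57, n)
    df["longitude"] = longitudes if longitudes is not None else np.linspace(16, 17, n)
    for j, var in enumerate(env_variables):
        if env is not None and var in env:
            df[var] = env[var]
        else:
            df[var] = rng.normal(size=n) + j
    return SampleMetadata(df, tuple(env_variables))


@pytest.fixture
def toy_metadata(toy_otu_table) -> SampleMetadata:
    return make_metadata(
        toy_otu_table.sample_ids, months=["April", "May", "May"]
    )


def random_distance_matrix(n, rng, ids=None):
    from metacomm.io_formats import DistanceMatrix

    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return DistanceMatrix(ids or [f"s{i}" for i in range(n)], a)
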