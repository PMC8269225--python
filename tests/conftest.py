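import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mycoweb as mw

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix():
    """3 OTUs x 2 samples with counts {{5,0},{1,2},{0,7}} (OTU-major)."""
    return mw.CommunityMatrix(
        sample_ids=["s1", "s2"],
        otu_ids=["o1", "o2", "o3"],
        counts=np.array([[5, 1, 0], [0, 2, 7]]),
    )


@pytest.fixture(scope="session")
def small_fixture():
    """Generated small metacommunity (30 sites x 150 OTUs) with ground truth."""
    return mw.generate_metacommunity(mw.small_config(seed=11))


@pytest.fixture(scope="session")
def small_pipeline(small_fixture):
    """Small fixture taken through rarefaction, filtering and the metaweb."""
    matrix, metadata, truth = small_fixture
    rare = mw.rarefy(matrix, depth=20_000, seed=11)
    filt = mw.prevalence_filter(rare, 0.02)
    presence = mw.to_presence(filt)
    assoc = mw.all_pair_associations(presence, alpha=0.05)
    web = mw.build_metaweb(assoc, filt.otu_ids, "ES")
    return {
        "matrix": rare,
        "filtered": filt,
        "presence": presence,
        "assoc": assoc,
        "web": web,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def standard_pipeline():
    """Standard benchmark (120 sites x 600 OTUs) taken through the metaweb."""
    matrix, metadata, truth = mw.generate_metacommunity(mw.standard_config(seed=1))
    rare = mw.rarefy(matrix, depth=20_000, seed=1)
    filt = mw.prevalence_filter(rare, 0.02)
    presence = mw.to_presence(filt)
    assoc = mw.all_pair_associations(presence, alpha=0.05)
    web = mw.build_metaweb(assoc, filt.otu_ids, "ES")
    profiles = mw.profile_all(web, presence)
    return {
        "presence": presence,
        "assoc": assoc,
        "web": web,
        "profiles": profiles,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture
def tiny_metaweb():
    """Hand-built metaweb: a positive triangle plus a negative edge."""
    return mw.Metaweb(
        stratum="toy",
        nodes=["a", "b", "c", "d", "e"],
        positive_edges=[("a", "b"), ("b", "c"), ("a", "c")],
        negative_edges=[("d", "e")],
    )


def random_graph(rng, n_nodes, p):
    """Edge list of an Erdos-Renyi graph over string node names."""
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                edges.append((f"n{i}", f"n{j}"))
    return edges
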