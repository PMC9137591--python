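import numpy as np
import pandas as pd
import pytest

from gutlinks import composition as comp
from gutlinks import diversity as dv
from gutlinks.io import Config
from gutlinks.simulate import default_design, simulate_counts


@pytest.fixture(scope="session")
def demo_dataset():
    """One simulated study dataset with planted structure (seed 1)."""
    design = default_design(seed=1)
    table, meta, tax, truth = simulate_counts(design)
    return {"design": design, "table": table, "meta": meta, "tax": tax, "truth": truth}


@pytest.fixture(scope="session")
def demo_rel_genus(demo_dataset):
    """Rarefied genus-level percent abundances of the demo dataset."""
    cfg = Config()
    table = dv.filter_low_abundance(demo_dataset["table"], cfg.min_feature_reads)
    rare = dv.rarefy(table, cfg.rarefaction_depth, seed=0)
    rel = comp.to_relative(comp.aggregate_to_rank(rare, demo_dataset["tax"], "genus"))
    meta = demo_dataset["meta"]
    meta = meta[meta["sample_id"].isin(rare.sample_ids)].reset_index(drop=True)
    return rel, meta


def random_distance_matrix(n, rng):
    """Euclidean distances of random points (valid metric for oracles)."""
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])
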