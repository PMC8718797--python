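import warnings

import numpy as np
import pytest

from lncdlink import (AssociationMatrix, DiseaseDAGSet, PipelineConfig,
                      PlantedWorld, generate, run_pipeline)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_dags():
    """d0 -> p -> g ancestor chain plus an unrelated disease d1."""
    return DiseaseDAGSet.from_edges([("d0", "p"), ("p", "g")], ["d0", "d1"])


@pytest.fixture
def diamond_dags():
    """d0 with parents p1, p2, both children of root r."""
    edges = [("d0", "p1"), ("d0", "p2"), ("p1", "r"), ("p2", "r")]
    return DiseaseDAGSet.from_edges(edges, ["d0"])


@pytest.fixture
def small_assoc():
    """4 lncRNAs x 3 diseases with a mix of degrees (no empty rows/cols)."""
    A = np.array([
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 1],
        [0, 0, 1],
    ])
    return AssociationMatrix(A, ["l0", "l1", "l2", "l3"], ["d0", "d1", "d2"])


@pytest.fixture(scope="session")
def small_world():
    """A small planted world every stage can run on quickly."""
    world = PlantedWorld(nl=24, nd=30, n_communities=3, p_in=0.5, p_out=0.05,
                         holdout_fraction=0.2, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(world)


@pytest.fixture(scope="session")
def small_pipeline(small_world):
    """Full pipeline on the small world at reduced hyperparameters."""
    A, dags, held = small_world
    cfg = PipelineConfig(dim=24, epochs=3, walks_per_node=5, walk_length=30,
                         n_estimators=25, k_clusters=5, kmeans_restarts=3,
                         folds=5, lr_max_steps=500, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(A, dags, cfg), held
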