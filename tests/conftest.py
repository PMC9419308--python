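import numpy as np
import pandas as pd
import pytest

import dietnet as dn


@pytest.fixture(scope="session")
def small_cohort() -> dn.SyntheticCohort:
    """One modest cohort with a planted saturated-fats effect, reused across tests."""
    cfg = dn.CohortConfig(
        n_subjects=600,
        seed=7,
        outcome_model=dn.OutcomeModel(
            intercept=-1.1,
            network_effects={"saturated_fats": dn.NetworkEffect(logor_t2=0.3, logor_t3=np.log(1.81))},
        ),
    )
    return dn.simulate_cohort(cfg)


@pytest.fixture
def pair_structure():
    """A single planted pair at rho=0.30 inside a 5-group vocabulary."""
    structure = dn.PlantedStructure(
        blocks=(dn.Block("pair", (("a", "b", 0.30),)),)
    )
    groups = ("a", "b", "c", "d", "e")
    marginals = {g: (10.0, 2.0) for g in groups}
    return structure, groups, marginals


def make_network(edges, rho=0.5):
    """Build a Network object from bare (a, b) edge tuples (helper for graph tests)."""
    nodes = tuple(sorted({n for e in edges for n in e}))
    full = tuple(sorted((min(a, b), max(a, b), rho, abs(rho) >= 0.30) for a, b in edges))
    return dn.Network(network_id="test", nodes=nodes, edges=full)


@pytest.fixture
def two_triangles():
    """Two triangles sharing one node v: the canonical overlapping-community case."""
    return make_network(
        [("a", "b"), ("a", "v"), ("b", "v"), ("v", "x"), ("v", "y"), ("x", "y")]
    )
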