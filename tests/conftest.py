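import numpy as np
import pandas as pd
import networkx as nx
import pytest

from femnet.simulate import CohortSpec, PlantedModule, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest matched cohort with a single planted anti-correlated module."""
    spec = CohortSpec(
        n_genes=200,
        n_normal=30,
        n_lumA=15,
        n_lumB=15,
        planted_modules=[PlantedModule(size=12, delta_D=1.5, delta_R=-1.5)],
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def weighted_path_graph():
    """Path a-b-c-d with known edge weights (node t_I set alongside)."""
    g = nx.Graph()
    g.add_edge("a", "b", weight=3.0)
    g.add_edge("b", "c", weight=1.0)
    g.add_edge("c", "d", weight=0.5)
    for n, v in zip("abcd", (4.0, 2.0, 0.0, 1.0)):
        g.nodes[n]["t_I"] = v
    return g


def two_group_phenotype(normals, tumours, subtypes=None):
    samples = list(normals) + list(tumours)
    phen = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["normal"] * len(normals) + ["tumour"] * len(tumours),
            "subtype": ["none"] * len(normals)
            + (subtypes if subtypes else ["none"] * len(tumours)),
        }
    )
    phen.index = samples
    return phen
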