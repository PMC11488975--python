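import pandas as pd
import pytest

from annosom import (
    AnnotationTree,
    ClusterExpressionMatrix,
    SimulationConfig,
    add_node,
    simulate_project,
)


@pytest.fixture(scope="session")
def sim_project():
    """Default synthetic project used across the suite (seed fixed)."""
    return simulate_project(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sim_expression(sim_project):
    return sim_project.expression_matrix()


@pytest.fixture()
def tiny_expression():
    """Four clusters, two markers, engineered for hand-checkable filtering."""
    values = pd.DataFrame(
        {
            "CD3": [0.9, 0.8, 0.1, 0.2],
            "CD19": [0.1, 0.1, 0.9, 0.1],
        },
        index=["k1", "k2", "k3", "k4"],
    )
    values.index.name = "cluster_id"
    # already on [0,1] with min 0.1/max 0.9 per column -> keep the raw values
    # as the "normalized" scale so thresholds of 0.5 mean what the tests say
    return ClusterExpressionMatrix(
        values=values, normalized=values.copy(), constant_markers=()
    )


@pytest.fixture()
def t_cell_tree(tiny_expression):
    tree = AnnotationTree(markers=tiny_expression.marker_names)
    add_node(tree, tree.root_id, "T cells", ["CD3"], ["CD19"])
    return tree
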