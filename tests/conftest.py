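import pytest
from hypothesis import HealthCheck, settings

import expertsde as es

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def chess_tree():
    """Symmetric canonical two-ply chess tree (all weights/values 1)."""
    return es.chess_scenario_tree()


@pytest.fixture
def chess_model(chess_tree):
    return es.ToMModel(tree=chess_tree, noise=1.0, beta=2.0, decision_threshold=3.0)


@pytest.fixture
def asymmetric_chess_model():
    """Chess scenario with the Knight line strictly favored."""
    tree = es.chess_scenario_tree(
        edge_weights={
            ("Nf6", "Nf6/Ng5"): 1.0,
            ("Nf6", "Nf6/Nc3"): 0.5,
            ("d6", "d6/c3"): 0.6,
            ("d6", "d6/h3"): 0.4,
        },
        leaf_values={
            "Nf6/Ng5/d5": 1.0, "Nf6/Ng5/Bc5": 0.5,
            "Nf6/Nc3/d5": 0.8, "Nf6/Nc3/Bc5": 0.2,
            "d6/c3/d5": 0.3, "d6/c3/Bc5": 0.1,
            "d6/h3/d5": 0.2, "d6/h3/Bc5": 0.4,
        },
    )
    return es.ToMModel(tree=tree, noise=1.0, beta=2.0, decision_threshold=3.0)
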