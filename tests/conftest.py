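import pytest

import meionet as mn


@pytest.fixture(scope="session")
def small_scenario() -> mn.Scenario:
    """A reduced four-study scenario used by cross-module tests."""
    return mn.generate_scenario(
        mn.ScenarioConfig(seed=7, n_metagenes=150, module_size=10)
    )


@pytest.fixture(scope="session")
def small_result(small_scenario) -> mn.pipeline.PipelineResult:
    return mn.run_scenario(small_scenario)


def hand_dag():
    """A hand-built 6-term is_a DAG with known term probabilities.

        root
        /  \
       A    B
      / \\   \
     C   D   E        (C, D under A; E under B)
    """
    import networkx as nx

    dag = nx.DiGraph()
    for term in ("root", "A", "B", "C", "D", "E"):
        dag.add_node(term, namespace="biological_process")
    dag.add_edge("A", "root")
    dag.add_edge("B", "root")
    dag.add_edge("C", "A")
    dag.add_edge("D", "A")
    dag.add_edge("E", "B")
    return dag


@pytest.fixture()
def six_term_resources():
    """GOResources on the hand DAG with a 10-gene corpus.

    Direct annotations: g1,g2 -> C; g3 -> D; g4 -> E; g5 -> A; g6..g10 -> B.
    """
    dag = hand_dag()
    annotations = {
        "g1": frozenset({"C"}),
        "g2": frozenset({"C"}),
        "g3": frozenset({"D"}),
        "g4": frozenset({"E"}),
        "g5": frozenset({"A"}),
        **{f"g{i}": frozenset({"B"}) for i in range(6, 11)},
    }
    corpus = set(annotations)
    return mn.build_go_resources(dag, annotations, corpus)
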