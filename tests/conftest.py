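import pytest

from haplocall.fixtures import SimulationSpec, build_tree, make_samples
from haplocall.phylotree import Node, PhyloTree


@pytest.fixture
def tiny_tree():
    """Hand-built 4-node tree: ROOT -> A(263G) -> A1(152C) -> A1a(263G!)."""
    from haplocall.variants import parse_variant as pv

    nodes = {
        "ROOT": Node("ROOT", None, (), ["A"]),
        "A": Node("A", "ROOT", (pv("263G"),), ["A1"]),
        "A1": Node("A1", "A", (pv("152C"),), ["A1a"]),
        "A1a": Node("A1a", "A1", (pv("263G!"),), []),
    }
    return PhyloTree(
        nodes=nodes,
        root="ROOT",
        reference="ACGT" * 200,
        clusters=["A"],
        name="tiny",
        version="1",
    )


@pytest.fixture(scope="session")
def default_spec():
    return SimulationSpec(seed=7)


@pytest.fixture(scope="session")
def synthetic_tree(default_spec):
    return build_tree(default_spec)


@pytest.fixture(scope="session")
def sample_batch(synthetic_tree, default_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("batch")
    return make_samples(synthetic_tree, default_spec, out)
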