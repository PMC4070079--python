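import numpy as np
import pytest

from bnboot import CPT, CategoricalVariable, DiscreteBayesianNetwork

# confidences of the six possible edges of the 4-node worked example,
# keyed by canonical pair
EXAMPLE_CONFIDENCES = {
    ("A", "B"): 0.2242,
    ("A", "C"): 0.0460,
    ("A", "D"): 0.8935,
    ("B", "C"): 0.3921,
    ("B", "D"): 0.7689,
    ("C", "D"): 0.9439,
}


@pytest.fixture
def example_vector():
    """The worked-example confidence vector in canonical pair order."""
    return np.array([EXAMPLE_CONFIDENCES[p] for p in sorted(EXAMPLE_CONFIDENCES)])


def make_chain_net(p_root=0.3, p_same=0.9, length=2):
    """Binary chain X0 -> X1 -> ... with P(child = parent's level) = p_same."""
    variables = [CategoricalVariable(f"X{i}", ("0", "1")) for i in range(length)]
    cpts = {"X0": CPT(parents=(), table=np.array([[p_root, 1 - p_root]]))}
    for i in range(1, length):
        cpts[f"X{i}"] = CPT(
            parents=(f"X{i-1}",),
            table=np.array([[p_same, 1 - p_same], [1 - p_same, p_same]]),
        )
    return DiscreteBayesianNetwork(variables=variables, cpts=cpts)


@pytest.fixture
def two_node_net():
    return make_chain_net(length=2)
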