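import numpy as np
import pytest

from grncontrol.network import Edge, NetworkSpec, Node


@pytest.fixture
def negative_feedback_spec() -> NetworkSpec:
    """Two-gene negative feedback loop: X->Y->Z with Z repressing Y.

    Rates d_y = d_z = 0.01/min, f_yz = 0.04, f_zy = 0.01, constant drive
    f_xy*x = 10 molecules/min into Y.
    """
    return NetworkSpec(
        name="negative_feedback",
        nodes=[Node(name="Y", degradation=0.01), Node(name="Z", degradation=0.01)],
        edges=[
            Edge(source="Y", target="Z", sign="activation", strength=0.04),
            Edge(source="Z", target="Y", sign="repression", strength=0.01),
        ],
        inputs={"Y": 10.0},
        input_node="Y",
        output_node="Z",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
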