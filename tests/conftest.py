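import pytest

from lans import WeightedNetwork, complex_star, simple_star


@pytest.fixture
def star():
    """Simple star (hub + 20-ring), spokes weight 2, ring weight 1."""
    net, red = simple_star(20)
    return net, set(red)


@pytest.fixture
def cstar():
    """Complex star (10 per tier): central 200/100, connectors 100, periphery 2/1."""
    net, red = complex_star(10)
    return net, set(red)


@pytest.fixture
def triangle():
    net = WeightedNetwork(directed=False)
    net.add_edge("a", "b", 3.0)
    net.add_edge("b", "c", 2.0)
    net.add_edge("a", "c", 1.0)
    return net
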