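import numpy as np
import pytest

from angioadapt import hemodynamics as hd
from angioadapt.fixtures import toy_network
from angioadapt.network import BOUNDARY, Network
from angioadapt.params import OxygenParameters
from angioadapt.tissue import rectangle_domain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_segment():
    return toy_network("single_segment")


@pytest.fixture
def y_bifurcation():
    return toy_network("Y_bifurcation")


@pytest.fixture
def parallel_loop():
    return toy_network("parallel_loop")


@pytest.fixture
def grid_mesh():
    return toy_network("grid_mesh")


def three_segment_toy():
    """3-segment vessel path crossing a 450x450 µm sheet (10x10 tissue grid).

    The path is offset from the tissue-point rows so every tissue point has
    at least ~25 µm clearance from the vessel axis.
    """
    net = Network()
    a = net.add_node(30, 275, BOUNDARY, bc_type="pressure", bc_value=59.09,
                     bc_hematocrit=0.3742, bc_po2=75.0)
    m1 = net.add_node(225, 275)
    m2 = net.add_node(225, 325)
    b = net.add_node(430, 325, BOUNDARY, bc_type="pressure", bc_value=15.0)
    net.add_segment(a, m1, 12.0, "arteriole")
    net.add_segment(m1, m2, 10.0, "capillary")
    net.add_segment(m2, b, 12.0, "venule")
    return net


@pytest.fixture(scope="session")
def oxygen_toy():
    """Solved flow + domain for the 3-segment oxygen-oracle geometry."""
    net = three_segment_toy()
    flow = hd.solve_flow(net)
    dom = rectangle_domain(450, 450)
    params = OxygenParameters(M0=1.0)
    return net, flow, dom, params
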