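"""Shared fixtures: toy networks and cached (expensive) simulations."""

import numpy as np
import pytest

import pulsetrim as pt
from pulsetrim.units import MMHG


@pytest.fixture(scope="session")
def blood():
    return pt.BloodProperties()


@pytest.fixture()
def single_vessel():
    return pt.make_fixture(pt.ToyNetworkSpec(family="single_vessel"))


@pytest.fixture()
def tree3():
    return pt.make_fixture(pt.ToyNetworkSpec(family="binary_tree", generations=3))


@pytest.fixture()
def ring():
    return pt.make_fixture(pt.ToyNetworkSpec(family="ring_with_outlets"))


@pytest.fixture()
def toy_coronary():
    return pt.make_fixture(pt.ToyNetworkSpec(family="toy_coronary"))


@pytest.fixture(scope="session")
def coarse_cfg_dict():
    """Coarse-but-adequate solver settings for pipeline-level tests."""
    return dict(dx_target=0.5, periodicity_tol=2e-3, max_cycles=15)


@pytest.fixture(scope="session")
def tree_baseline():
    """Binary-tree network with a converged pulsatile baseline solution."""
    net = pt.make_fixture(pt.ToyNetworkSpec(family="binary_tree", generations=3))
    terminals = ["s00", "s01", "s10", "s11"]
    sites = [("s", 0.0), ("s", 0.5), ("s", 1.0)] + [(t, 1.0) for t in terminals]
    cfg = pt.SolverConfig(output_sites=sites)
    result = pt.run_simulation(net, cfg)
    assert result.converged
    return net, result


from pulsetrim.testkit import random_tree  # noqa: E402,F401  (test helper)
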