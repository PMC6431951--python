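"""Shared fixtures. Chain fixtures are session-scoped: construction and
localization are the expensive parts of the suite."""

import numpy as np
import pytest

from knotchain.model_core import Conformation, ModelParams
from knotchain.synthetic_data import (
    KnotSpec,
    build_two_knot_chain,
    make_torus_trefoil,
    relax_minimize,
)


@pytest.fixture(scope="session")
def desk_params():
    """Desk-scale two-knot system: N = 100, L = 70 sigma (same ~0.7
    extension ratio as the production N = 300, L = 205 system)."""
    return ModelParams(N=100, L_wall=70.0, kappa_b=20.0)


@pytest.fixture(scope="session")
def small_params():
    return ModelParams(N=10, L_wall=12.0, kappa_b=3.0)


@pytest.fixture(scope="session")
def trefoil_ring():
    """Closed right-handed trefoil polygon, 60 beads at unit bond."""
    return make_torus_trefoil(60, handedness=1, scale=1.0)


@pytest.fixture(scope="session")
def chain_pp(desk_params):
    """(+,+) separated two-knot chain."""
    return build_two_knot_chain(
        desk_params, KnotSpec(1, 25, 24), KnotSpec(1, 70, 24)
    )


@pytest.fixture(scope="session")
def chain_pm(desk_params):
    """(+,-) separated two-knot chain."""
    return build_two_knot_chain(
        desk_params, KnotSpec(1, 25, 24), KnotSpec(-1, 70, 24)
    )


@pytest.fixture(scope="session")
def chain_pm_nested(desk_params):
    """(+,-) intertwined chain: the '-' knot nested inside the '+'."""
    return build_two_knot_chain(
        desk_params, KnotSpec(1, 50, 24), KnotSpec(-1, 50, 24), intertwined=True
    )


@pytest.fixture(scope="session")
def chain_pm_relaxed(desk_params, chain_pm):
    return relax_minimize(chain_pm, desk_params, 800)


@pytest.fixture(scope="session")
def chain80_pp():
    """Compact (<= 80 bead) separated (+,+) fixture for the exhaustive
    localization oracle."""
    params = ModelParams(N=80, L_wall=40.0, kappa_b=20.0)
    return build_two_knot_chain(
        params, KnotSpec(1, 20, 24), KnotSpec(1, 56, 24)
    )


@pytest.fixture(scope="session")
def chain80_nested():
    params = ModelParams(N=80, L_wall=40.0, kappa_b=20.0)
    return build_two_knot_chain(
        params, KnotSpec(1, 40, 24), KnotSpec(-1, 40, 24), intertwined=True
    )


@pytest.fixture(scope="session")
def single_knot_chain80():
    """One trefoil spliced into a 60-bead stretched chain (hand
    assembly from the template, independent of build_two_knot_chain)."""
    from knotchain.synthetic_data import _lollipop_template

    tpl = _lollipop_template(KnotSpec(1, 30, 24))
    n, b_s = 60, 1.0
    lead = np.zeros((20, 3))
    lead[:, 0] = b_s * np.arange(20)
    placed = tpl - tpl[0] + np.array([lead[-1, 0] + b_s, 0.0, 0.0])
    n_tail = n - 20 - len(tpl)
    tail = np.zeros((n_tail, 3))
    tail[:, 0] = placed[-1, 0] + b_s * (1 + np.arange(n_tail))
    return Conformation(np.vstack([lead, placed, tail]))


def straight_chain(n, bond=1.0, x0=0.0, axis=0):
    pos = np.zeros((n, 3))
    pos[:, axis] = x0 + bond * np.arange(n)
    return Conformation(pos)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
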