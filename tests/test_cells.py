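"""Cell-level dynamics: gamma law, right-hand side, coupling operator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from avnode.cells import (
    CellParams,
    CellState,
    LinkSpec,
    InvalidParameterError,
    apply_gamma,
    cell_rhs,
    coupling_current,
)
from avnode.engine import integrate
from avnode.topology import NodeTopology


@pytest.mark.parametrize(
    "mu1, mu2, gamma, expected",
    [
        (0.2, 0.3, 1.0, (0.2, 0.3)),      # identity at gamma = 1
        (0.2, 0.3, 2.0, (0.1, 0.6)),      # vagal: mu1 halves, mu2 doubles
        (0.2, 0.3, 0.5, (0.4, 0.15)),     # sympathetic: the reverse
    ],
)
def test_apply_gamma_values(mu1, mu2, gamma, expected):
    assert apply_gamma(mu1, mu2, gamma) == pytest.approx(expected)


@pytest.mark.parametrize("gamma", [0.0, -1.0])
def test_apply_gamma_rejects_nonpositive(gamma):
    with pytest.raises(InvalidParameterError):
        apply_gamma(0.2, 0.3, gamma)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    mu1=st.floats(0.01, 1.0),
    mu2=st.floats(0.05, 1.0),
    g1=st.floats(0.5, 2.0),
    g2=st.floats(0.5, 2.0),
)
def test_apply_gamma_composes_multiplicatively(mu1, mu2, g1, g2):
    """Scaling by g1 then g2 equals scaling by g1*g2."""
    step = apply_gamma(*apply_gamma(mu1, mu2, g1), g2)
    direct = apply_gamma(mu1, mu2, g1 * g2)
    assert step == pytest.approx(direct, rel=1e-12)


QUIESCENT = dict(a1=0.13, a2=0.1, k=8.0, c=1.0, eps0=0.01, mu1=0.2, mu2=0.3,
                 is_pacemaker=False)


def test_rhs_quiescent_equilibrium():
    """(V, r) = (0, 0) is a rest state of an excitable cell."""
    p = CellParams(**QUIESCENT)
    assert cell_rhs(CellState(0.0, 0.0), p) == (0.0, 0.0)


def test_rhs_voltage_term_hand_value():
    # dV/dt = k*V*(V-a1)*(1-V) = 8*0.5*0.45*0.5 = 0.9 at V=0.5, r=0
    p = CellParams(**{**QUIESCENT, "a1": 0.05})
    dV, _ = cell_rhs(CellState(0.5, 0.0), p)
    assert dV == pytest.approx(8 * 0.5 * 0.45 * 0.5)


def test_rhs_gate_term_hand_value():
    # dr/dt = c*eps0*(-r - k*V*(V-a2-1)) = 1*0.01*(8*0.5*0.6) = 0.024
    p = CellParams(**{**QUIESCENT, "a2": 0.1, "eps0": 0.01})
    _, dr = cell_rhs(CellState(0.5, 0.0), p)
    assert dr == pytest.approx(0.024)


def test_rhs_gamma_enters_only_through_mu():
    p = CellParams(**QUIESCENT)
    s = CellState(0.3, 0.5)
    base = cell_rhs(s, p, gamma=1.0)
    scaled = cell_rhs(s, p.with_(mu1=p.mu1 / 1.4, mu2=p.mu2 * 1.4), gamma=1.0)
    via_gamma = cell_rhs(s, p, gamma=1.4)
    assert via_gamma == pytest.approx(scaled)
    assert via_gamma[1] != pytest.approx(base[1])


def test_coupling_homogeneous_symmetric_is_zero():
    link = LinkSpec("a", "b", d=0.3, beta=1.0)
    assert coupling_current(0.7, incoming=[(0.7, link)], outgoing=[(0.7, link)]) == 0.0


def test_coupling_chain_hand_values():
    up = LinkSpec("u", "c", d=0.1, beta=1.0)
    dn = LinkSpec("c", "d", d=0.1, beta=1.0)
    assert coupling_current(0.0, incoming=[(1.0, up)], outgoing=[(0.0, dn)]) == pytest.approx(0.1)
    # asymmetric: beta=0.5 on the incoming link
    up2 = LinkSpec("u", "c", d=0.1, beta=0.5)
    assert coupling_current(1.0, incoming=[(0.0, up2)], outgoing=[(0.0, dn)]) == pytest.approx(-0.15)


def test_coupling_two_cell_antisymmetry():
    """With beta = 1 the current leaving one cell enters the other."""
    link = LinkSpec("a", "b", d=0.25, beta=1.0)
    Va, Vb = 0.9, 0.2
    into_b = coupling_current(Vb, incoming=[(Va, link)])
    into_a = coupling_current(Va, outgoing=[(Vb, link)])
    assert into_a == pytest.approx(-into_b)


@pytest.mark.parametrize(
    "bad",
    [
        dict(k=-1.0), dict(c=0.0), dict(mu2=0.0), dict(eps0=-0.1),
        dict(a1=-0.1),                       # pacemaker flag inconsistent
        dict(a1=0.1, is_pacemaker=True),
    ],
)
def test_cell_params_validation(bad):
    with pytest.raises(InvalidParameterError):
        CellParams(**{**QUIESCENT, **bad})


def _single_cell_topo(params_row):
    cells = pd.DataFrame([dict(id="SN1", segment="SN", **params_row)])
    links = pd.DataFrame(columns=["from_cell", "to_cell", "d", "beta"])
    return NodeTopology.from_frames(cells, links, time_scale=1.0)


def test_excitable_cell_returns_to_rest():
    """A super-threshold kick produces one action potential and the cell
    settles back to within 1e-6 of the rest state."""
    topo = _single_cell_topo(dict(a1=0.13, a2=0.1, k=8.0, c=1.0, eps0=0.01,
                                  mu1=0.2, mu2=0.3, is_pacemaker=0,
                                  gamma_controlled=1))
    state = np.array([[0.35], [0.0]])      # above threshold a1
    res = integrate(topo, 1.0, t_span=2000.0, initial_state=state)
    assert len(res.events) == 1
    assert abs(res.final_state).max() < 1e-6


def test_pacemaker_period_increases_with_gamma():
    """An isolated pacemaker cell oscillates strictly periodically and
    slows monotonically as vagal tone (gamma) rises."""
    topo = _single_cell_topo(dict(a1=-0.0895, a2=0.2, k=8.0, c=1.0, eps0=0.0075,
                                  mu1=0.01, mu2=0.2, is_pacemaker=1,
                                  gamma_controlled=1))
    periods = []
    for gamma in (0.5, 0.8, 1.2, 1.6, 2.0):
        res = integrate(topo, gamma, t_span=4000.0)
        t = res.events_of("SN1")
        t = t[t > 1000.0]
        iv = np.diff(t)
        assert len(iv) >= 3
        assert iv.std() / iv.mean() < 1e-3          # strictly periodic
        periods.append(iv.mean())
    assert all(b > a for a, b in zip(periods, periods[1:]))
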