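"""Aliev--Panfilov cell dynamics with autonomic (gamma) modulation.

Each cell of the conduction-system model is a two-variable excitable /
oscillatory unit

    dV/dt = c [ k V (V - a1) (1 - V) - r V ] + I_coupl + I_stim
    dr/dt = c eps(V, r) [ -r - k V (V - a2 - 1) ],
    eps(V, r) = eps0 + r mu1* / (V + mu2*),

where ``V`` is the dimensionless transmembrane potential and ``r`` the
recovery (gate) variable.  Quiescent excitable cells have ``a1 > 0`` (the
excitation threshold); pacemaker cells have ``a1 < 0``, which destabilises
the resting state and produces a relaxation limit cycle whose period sets
the intrinsic pacemaker rate.

Autonomic tone enters through a single coefficient ``gamma`` that rescales
the two refractoriness parameters,

    mu1* = mu1 / gamma,      mu2* = mu2 * gamma,

so that small ``gamma`` (sympathetic dominance) shortens refractory periods
and speeds pacemakers, and large ``gamma`` (vagal dominance) does the
opposite.  Only cells with ``gamma_controlled=True`` (sinus node through
penetrating bundle) see gamma != 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "CellParams",
    "CellState",
    "LinkSpec",
    "apply_gamma",
    "cell_rhs",
    "coupling_current",
    "V_BOUNDS",
    "EPS_DENOM_FLOOR",
]

#: Physiological bounds for the dimensionless potential.  Leaving this
#: interval on any packaged parameter set indicates a simulation error.
V_BOUNDS = (-0.5, 1.5)

#: Floor applied to the denominator V + mu2* when evaluating eps.
EPS_DENOM_FLOOR = 1e-9


class InvalidParameterError(ValueError):
    """A cell, link or gamma parameter violates its constraints."""


@dataclass(frozen=True)
class CellParams:
    """Parameter set of a single Aliev--Panfilov cell.

    Attributes
    ----------
    a1 : float
        Excitation threshold (``a1 > 0``, quiescent cell) or pacemaker
        frequency parameter (``a1 < 0``).
    a2 : float
        Recovery offset in the gate equation.
    k : float
        Magnitude of the transmembrane current.
    c : float
        Time-scaling coefficient of the cell (per model time unit).
    eps0 : float
        Baseline rate of the gate variable.
    mu1, mu2 : float
        Refractoriness parameters; these are the two parameters rescaled
        by the autonomic coefficient gamma.
    is_pacemaker : bool
        True iff the cell self-oscillates (must agree with sign of a1).
    gamma_controlled : bool
        True for cells under autonomic control (SN through PB).
    """

    a1: float
    a2: float
    k: float
    c: float
    eps0: float
    mu1: float
    mu2: float
    is_pacemaker: bool = False
    gamma_controlled: bool = True

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.c > 0 and self.mu2 > 0):
            raise InvalidParameterError(
                f"k, c, mu2 must be positive (got k={self.k}, c={self.c}, mu2={self.mu2})"
            )
        if self.eps0 < 0 or self.mu1 < 0:
            raise InvalidParameterError("eps0 and mu1 must be non-negative")
        if self.a1 == 0:
            raise InvalidParameterError("a1 must be non-zero (sign selects pacemaker vs quiescent)")
        if self.is_pacemaker != (self.a1 < 0):
            raise InvalidParameterError(
                f"is_pacemaker={self.is_pacemaker} inconsistent with a1={self.a1}"
            )

    def with_(self, **kwargs) -> "CellParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class CellState:
    """Instantaneous state (V, r) of one cell."""

    V: float = 0.0
    r: float = 0.0


@dataclass(frozen=True)
class LinkSpec:
    """Directed coupling link between two cells.

    ``from_cell -> to_cell`` is the anterograde direction (sinus node
    toward His bundle).  ``d`` is the diffusion (conductance) coefficient
    and ``beta`` the asymmetry coefficient: ``beta < 1`` accelerates
    anterograde and slows retrograde conduction, and vice versa.
    """

    from_cell: str
    to_cell: str
    d: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise InvalidParameterError(f"link {self.from_cell}->{self.to_cell}: d must be >= 0")
        if self.beta <= 0:
            raise InvalidParameterError(f"link {self.from_cell}->{self.to_cell}: beta must be > 0")

    def with_(self, **kwargs) -> "LinkSpec":
        return replace(self, **kwargs)


def apply_gamma(mu1: float, mu2: float, gamma: float) -> tuple[float, float]:
    """Rescale the refractoriness parameters by the autonomic coefficient.

    Returns ``(mu1 / gamma, mu2 * gamma)``.  For cells outside autonomic
    control the caller passes ``gamma = 1``.
    """
    if gamma <= 0:
        raise InvalidParameterError(f"gamma must be positive, got {gamma}")
    return mu1 / gamma, mu2 * gamma


def cell_rhs(
    state: CellState,
    params: CellParams,
    I_coupl: float = 0.0,
    I_stim: float = 0.0,
    gamma: float = 1.0,
) -> tuple[float, float]:
    """Right-hand side (dV/dt, dr/dt) of one cell.

    Reference (scalar) implementation; the integration kernel evaluates
    the same algebra vectorised over the whole network.
    """
    mu1s, mu2s = apply_gamma(params.mu1, params.mu2, gamma)
    V, r = state.V, state.r
    dV = params.c * (params.k * V * (V - params.a1) * (1.0 - V) - r * V) + I_coupl + I_stim
    denom = V + mu2s
    if denom < EPS_DENOM_FLOOR:
        denom = EPS_DENOM_FLOOR
    eps = params.eps0 + r * mu1s / denom
    dr = params.c * eps * (-r - params.k * V * (V - params.a2 - 1.0))
    return dV, dr


def coupling_current(
    V_cell: float,
    incoming: Iterable[tuple[float, LinkSpec]] = (),
    outgoing: Iterable[tuple[float, LinkSpec]] = (),
) -> float:
    """Total coupling current into one cell of the branched network.

    For each incoming (anterograde) link with upstream potential ``V_up``
    the contribution is ``d * (V_up - beta * V_cell)``; for each outgoing
    link with downstream potential ``V_dn`` it is ``d * (-V_cell + beta *
    V_dn)``.  On an unbranched run of cells this reduces to the familiar
    asymmetric chain coupling

        I_i = d_{i-1} (V_{i-1} - beta_{i-1} V_i) + d_i (-V_i + beta_i V_{i+1}).

    Junction cells (the atrial branch point and the penetrating bundle)
    simply sum contributions over all incident links.
    """
    total = 0.0
    for V_up, link in incoming:
        total += link.d * (V_up - link.beta * V_cell)
    for V_dn, link in outgoing:
        total += link.d * (-V_cell + link.beta * V_dn)
    return total
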