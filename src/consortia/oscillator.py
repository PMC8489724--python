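"""Reduced fast–slow relaxation-oscillator model of the consortial oscillator.

The two-strain consortium with quorum-sensing-coupled division-length control
admits a two-variable reduction: ``x`` is the position of the strain interface
in a one-dimensional trap (``x = 1`` means the blue strain fills the trap) and
``Q`` is a binary-like memory variable encoding which strain is currently in
the reduced-division-length (short, disordered, pushing) state — ``Q = 1``
means the blue strain is short and advancing.

The dynamics are

    dx/dt = Q*x - (1 - Q)*(1 - x)
    dQ/dt = (1/eps) * (-Q * L1(x) + (1 - Q) * L2(x))

with inverting Hill switches

    L1(x) = 1 / (1 + ((1 - x)/(1 - K2))**n)
    L2(x) = 1 / (1 + (x/K1)**n)

``L1`` fires when the interface approaches the right trap edge (x -> 1,
i.e. x past K2) and resets Q to 0; ``L2`` fires near the left edge (x below
K1) and sets Q to 1.  Oscillation requires ``K1 < K2`` so the two switching
locations delimit a bistable band that the interface traverses slowly.

In the singular limit (eps -> 0, n -> inf) the half-cycles are pure
exponentials and the period has the closed form

    T = ln(K2/K1) + ln((1 - K1)/(1 - K2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "OscParams",
    "OscState",
    "hill_switches",
    "rhs",
    "integrate",
    "measure_period",
    "limit_period",
]


@dataclass(frozen=True)
class OscParams:
    """Parameters of the reduced oscillator.

    K1, K2 : switching positions of the interface, 0 < K1 < K2 < 1 for
        sustained oscillation (K1 > K2 is accepted and yields a non-oscillating
        system, useful for the failure-mode check).
    n : Hill exponent of the switches.
    eps : timescale separation; Q relaxes a factor 1/eps faster than x.
    """

    K1: float = 0.2
    K2: float = 0.8
    n: float = 8.0
    eps: float = 1e-2
    rtol: float = 1e-8
    atol: float = 1e-10

    # eps must stay LARGE relative to the Hill-function tails for Q to hold
    # its memory between switches: in the mid-band both switches leak at rate
    # ~ ((K1/K2-ish ratio)**n)/eps, so decreasing eps at fixed n eventually
    # destroys the bistable band.  The default pairs eps = 1e-2 with n = 8;
    # sharper switches (larger n) admit proportionally smaller eps.

    def __post_init__(self) -> None:
        if not (0.0 < self.K1 < 1.0) or not (0.0 < self.K2 < 1.0):
            raise ValueError("K1 and K2 must lie strictly inside (0, 1)")
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class OscState:
    x: float = 0.5
    Q: float = 0.0


def hill_switches(x: float, params: OscParams) -> tuple[float, float]:
    """Evaluate the two inverting Hill switches (L1, L2) at interface position x.

    L1 = 1/2 exactly at x = K2; L2 = 1/2 exactly at x = K1.
    """
    n = params.n
    # Guard the 0**n / division corner cases at the domain ends.
    one_minus = max(1.0 - x, 0.0)
    l1 = 1.0 / (1.0 + (one_minus / (1.0 - params.K2)) ** n)
    l2 = 1.0 / (1.0 + (max(x, 0.0) / params.K1) ** n)
    return l1, l2


def rhs(state: OscState | tuple[float, float], params: OscParams) -> tuple[float, float]:
    """Right-hand side (dx/dt, dQ/dt) of the reduced model."""
    if isinstance(state, OscState):
        x, q = state.x, state.Q
    else:
        x, q = state
    l1, l2 = hill_switches(x, params)
    dx = q * x - (1.0 - q) * (1.0 - x)
    dq = (-q * l1 + (1.0 - q) * l2) / params.eps
    return dx, dq


def integrate(
    params: OscParams,
    init: OscState | None = None,
    T: float = 20.0,
    n_points: int = 4000,
) -> "np.recarray":
    """Integrate the oscillator over [0, T] with a stiff-capable adaptive solver.

    Returns a record array with fields ``t``, ``x``, ``Q`` at dense output
    points (uniform grid of ``n_points``).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if init is None:
        init = OscState()

    def f(t, y):
        dx, dq = rhs((y[0], y[1]), params)
        # the interface front is confined to the trap: project onto [0, 1]
        if (y[0] <= 0.0 and dx < 0.0) or (y[0] >= 1.0 and dx > 0.0):
            dx = 0.0
        return dx, dq

    t_eval = np.linspace(0.0, T, n_points)
    sol = solve_ivp(
        f,
        (0.0, T),
        [init.x, init.Q],
        method="LSODA",
        t_eval=t_eval,
        rtol=params.rtol,
        atol=params.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0}: {sol.message}"
        )
    out = np.recarray(len(sol.t), dtype=[("t", float), ("x", float), ("Q", float)])
    out.t = sol.t
    out.x = sol.y[0]
    out.Q = sol.y[1]
    return out


def measure_period(series) -> tuple[float, tuple[float, float]]:
    """Measure the oscillation period from a (t, x, Q) series.

    Events are crossings of Q through 1/2: the period is the mean interval
    between successive upward crossings; the two half-cycle durations are the
    mean Q>1/2 and Q<1/2 residence times between events.

    Raises ``ValueError`` when fewer than two full cycles are present.
    """
    t = np.asarray(series.t if hasattr(series, "t") else series[0], dtype=float)
    q = np.asarray(series.Q if hasattr(series, "Q") else series[1], dtype=float)
    above = q > 0.5
    flips = np.flatnonzero(above[1:] != above[:-1])
    if flips.size == 0:
        raise ValueError("no Q = 1/2 crossings in series")
    # Linear interpolation of each crossing time.
    cross_t = t[flips] + (0.5 - q[flips]) * (t[flips + 1] - t[flips]) / (
        q[flips + 1] - q[flips]
    )
    upward = ~above[flips]  # crossing from below
    up_t = cross_t[upward]
    down_t = cross_t[~upward]
    if up_t.size < 3:
        raise ValueError("need at least two full cycles (three upward crossings)")
    period = float(np.mean(np.diff(up_t)))
    # Half-cycles: pair each upward crossing with the following downward one.
    highs, lows = [], []
    for tu0, tu1 in zip(up_t[:-1], up_t[1:]):
        mid = down_t[(down_t > tu0) & (down_t < tu1)]
        if mid.size:
            highs.append(mid[0] - tu0)
            lows.append(tu1 - mid[0])
    return period, (float(np.mean(highs)), float(np.mean(lows)))


def limit_period(params: OscParams) -> float:
    """Closed-form period in the singular limit eps -> 0, n -> inf.

    With Q pinned at 1 the interface obeys dx/dt = x between K1 and K2
    (duration ln(K2/K1)); with Q = 0, d(1-x)/dt = (1-x) between 1-K2 and
    1-K1 (duration ln((1-K1)/(1-K2))).
    """
    return math.log(params.K2 / params.K1) + math.log(
        (1.0 - params.K1) / (1.0 - params.K2)
    )
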