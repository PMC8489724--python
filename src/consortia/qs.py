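"""Quorum-sensing communication and the co-repressive division-length circuit.

Each strain constitutively produces an orthogonal acyl-homoserine-lactone
signal (blue -> C4HSL, orange -> C14HSL) unless repressed by its own LacI.
Signals cross the membrane with first-order exchange kinetics (rate ``d``,
larger for the smaller C4HSL molecule), pool in a well-mixed trap compartment
coupled to a flow-channel compartment, and are diluted from the channel by
media flow at rate ``gamma``.  The received (opposite-strain) signal drives
LacI expression through an activating Hill function; LacI represses the cell's
own signal production through an inverting Hill function; and when the
received signal exceeds the threshold ``H_T`` the cell's mean division length
is reduced by the factor ``a``.  The resulting negative-feedback toggle makes
the short, disordered strain eject its opponent until the opponent's signal
collapses, at which point the roles swap — a consortial strain-fraction
relaxation oscillator.

Intracellular state lives in ``ABMState.species`` columns (C4, C14, LacI);
all kinetics are integrated with forward Euler at the mechanics step, which is
short compared to every kinetic timescale used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abm import ABMParams, ABMState, simulate_abm, snapshot

__all__ = [
    "QSParams",
    "ExternalField",
    "update_intracellular",
    "update_external",
    "threshold_controller",
    "reduction_flags",
    "run_oscillator",
    "OscillatorResult",
]

C4, C14, LACI = 0, 1, 2
_PRODUCT = {0: C4, 1: C14}  # strain id -> molecule produced


@dataclass(frozen=True)
class QSParams:
    """Rates are per minute; concentrations in arbitrary units scaled so a
    fully producing half-trap population sustains an external signal of order
    0.5 at the default dilution."""

    alpha: tuple[float, float] = (1.0, 1.0)  # production (C4, C14)
    d: tuple[float, float] = (2.0, 1.0)  # membrane exchange (C4 faster)
    gamma: float = 0.5  # channel dilution
    k_ex: float = 1.0  # trap <-> channel exchange
    channel_volume_ratio: float = 2.0  # channel volume / trap volume
    K_L: float = 0.2  # LacI repression constant on own production
    m_L: float = 4.0
    beta: float = 0.3  # LacI synthesis scale
    K_H: float = 0.8  # opposite-signal activation constant for LacI
    m_H: float = 8.0
    delta_L: float = 0.15  # LacI decay
    H_T: float = 0.45  # division-length reduction threshold

    # The defaults implement the latch-then-release logic of the toggle: a
    # latched (repressed, shortened) strain stays latched while the opponent
    # signal exceeds K_H, which happens while the opponent holds well above a
    # third of the trap; H_T sits well below K_H so division-length reduction
    # is robustly ON during a latched phase and engages quickly on the other
    # strain after release.

    def __post_init__(self) -> None:
        for v in (*self.alpha, *self.d, self.gamma, self.k_ex, self.beta,
                  self.delta_L):
            if v < 0:
                raise ValueError("rates must be non-negative")
        if self.H_T <= 0:
            raise ValueError("threshold H_T must be positive")


@dataclass
class ExternalField:
    """Well-mixed external concentrations, per molecule (C4, C14)."""

    H_trap: np.ndarray = field(default_factory=lambda: np.zeros(2))
    H_channel: np.ndarray = field(default_factory=lambda: np.zeros(2))


def _clip_log(arr, label, log) -> None:
    neg = arr < 0
    if neg.any():
        if log is not None:
            log.append(f"clipped {int(neg.sum())} negative {label} values")
        arr[neg] = 0.0


def update_intracellular(
    state: ABMState, external: ExternalField, dt: float, params: QSParams,
    log: list | None = None,
) -> ABMState:
    """Forward-Euler step of per-cell signal and LacI kinetics.

    Own-molecule production is Hill-repressed by LacI; both molecules exchange
    with the trap pool; LacI is Hill-activated by the opposite-strain signal
    and decays first-order.  Negative values after a step are clipped to zero
    and logged (step-size warning).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.n == 0:
        return state
    sp = state.species
    laci = sp[:, LACI]
    own = np.array([_PRODUCT[int(s)] for s in state.strain])
    opp = 1 - own
    idx = np.arange(state.n)
    h_own = sp[idx, own]
    h_opp = sp[idx, opp]
    alpha = np.asarray(params.alpha)[own]
    d_own = np.asarray(params.d)[own]
    d_opp = np.asarray(params.d)[opp]
    repress = 1.0 / (1.0 + (laci / params.K_L) ** params.m_L)
    d_h_own = alpha * repress + d_own * (external.H_trap[own] - h_own)
    d_h_opp = d_opp * (external.H_trap[opp] - h_opp)
    act = h_opp**params.m_H / (params.K_H**params.m_H + h_opp**params.m_H)
    d_laci = params.beta * act - params.delta_L * laci
    sp[idx, own] = h_own + dt * d_h_own
    sp[idx, opp] = h_opp + dt * d_h_opp
    sp[:, LACI] = laci + dt * d_laci
    _clip_log(sp, "intracellular", log)
    return state


def update_external(
    state: ABMState, external: ExternalField, dt: float, params: QSParams,
    trap_area: float, log: list | None = None,
) -> ExternalField:
    """Forward-Euler step of the trap and flow-channel compartments.

    The trap pool integrates the volume-weighted membrane flux from all cells
    (cell volume taken proportional to length) and exchanges with the channel,
    which is diluted by media flow; with gamma = 0 and no production the total
    signal mass in the two compartments is conserved.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    flux = np.zeros(2)
    if state.n:
        own = np.array([_PRODUCT[int(s)] for s in state.strain])
        for m in (C4, C14):
            h_m = state.species[:, m]
            flux[m] = params.d[m] * np.sum(
                state.length * (h_m - external.H_trap[m])
            ) / trap_area
    dh_trap = flux - params.k_ex * (external.H_trap - external.H_channel)
    dh_chan = (
        params.k_ex / params.channel_volume_ratio
        * (external.H_trap - external.H_channel)
        - params.gamma * external.H_channel
    )
    external.H_trap = external.H_trap + dt * dh_trap
    external.H_channel = external.H_channel + dt * dh_chan
    _clip_log(external.H_trap, "trap", log)
    _clip_log(external.H_channel, "channel", log)
    return external


def threshold_controller(
    h_opp: float, lbar_d: float, params: QSParams, a: float
) -> float:
    """Effective mean division length of one cell: a*lbar_d while the
    received opposite-strain signal exceeds H_T (strictly), else lbar_d."""
    return a * lbar_d if h_opp > params.H_T else lbar_d


def reduction_flags(state: ABMState, params: QSParams) -> np.ndarray:
    """Per-cell division-length reduction flags from the current intracellular
    opposite-strain signal (strict threshold)."""
    own = np.array([_PRODUCT[int(s)] for s in state.strain])
    h_opp = state.species[np.arange(state.n), 1 - own]
    return h_opp > params.H_T


@dataclass
class OscillatorResult:
    series: pd.DataFrame  # t, fraction_orange, laci_blue, laci_orange, H ...
    snapshots: list
    status: str  # "ok" | "extinction"
    extinct_strain: int | None = None


def run_oscillator(
    abm_params: ABMParams,
    qs_params: QSParams = QSParams(),
    n_seed: int = 32,
    t_end: float = 900.0,
    sample_interval: float = 5.0,
    seed: int | np.random.Generator = 0,
    dt: float | None = None,
) -> OscillatorResult:
    """Full ABM + QS co-simulation of the consortial oscillator.

    Seeds the trap with two strains in separate halves, couples the
    division-length controller to the signaling field, and records per-strain
    mean LacI, received signals, and the strain fraction.  Terminates with
    status "extinction" if a strain vanishes (the failure mode of a threshold
    set too low).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .abm import seed_cells, step_abm

    state = seed_cells(abm_params, n_seed, "separated", rng)
    external = ExternalField()
    dt = abm_params.dt if dt is None else dt
    trap_area = abm_params.geometry.width * abm_params.geometry.height
    log: list[str] = []

    def qs_update(st: ABMState) -> ABMState:
        update_intracellular(st, external, dt, qs_params, log)
        update_external(st, external, dt, qs_params, trap_area, log)
        st.reduced = reduction_flags(st, qs_params)
        return st

    records = []
    snaps = []
    next_sample = 0.0
    status = "ok"
    extinct = None
    n_steps = int(round(t_end / dt))
    for k in range(n_steps + 1):
        if state.time >= next_sample - 1e-9:
            row = {"t": state.time, "H_trap_C4": external.H_trap[C4],
                   "H_trap_C14": external.H_trap[C14]}
            for sid, name in ((0, "blue"), (1, "orange")):
                mask = state.strain == sid
                row[f"n_{name}"] = int(mask.sum())
                row[f"laci_{name}"] = (
                    float(state.species[mask, LACI].mean()) if mask.any() else np.nan
                )
            tot = row["n_blue"] + row["n_orange"]
            row["fraction_orange"] = row["n_orange"] / tot if tot else np.nan
            records.append(row)
            snaps.append(snapshot(state))
            next_sample += sample_interval
        present = np.unique(state.strain)
        if state.time > 60.0 and len(present) < 2:
            status = "extinction"
            extinct = int({0, 1}.difference(present.tolist()).pop())
            break
        if k == n_steps:
            break
        state, _ = step_abm(state, abm_params, rng, dt, qs_update)
    series = pd.DataFrame(records)
    return OscillatorResult(series, snaps, status, extinct)
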