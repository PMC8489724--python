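"""Agent-based model of rod-shaped bacteria in an open monolayer trap.

Cells are 2D spherocylinders of constant 1 um width growing exponentially in
length (doubling time 20 min by default) inside an open rectangular trapping
region; cells whose centers leave the trap are washed away, keeping the
population roughly constant once the trap has filled.  A cell divides when its
length reaches its division target

    l_d = sqrt(2 * l0) * sqrt(lbar_d_effective),

where ``l0`` is the cell's birth length and ``lbar_d_effective`` the current
mean division length of its strain; daughters receive random birth fractions
``eps0`` and ``1 - eps0`` of the mother length with eps0 ~ U[0.45, 0.55],
which desynchronizes divisions across the population, and split the mother's
intracellular content in proportion to their birth lengths.  Mean division
length can be reduced by a factor ``a`` at a scheduled induction time or, in
quorum-sensing runs, per cell by a threshold controller.

Mechanical interactions are handled by :mod:`consortia.mechanics`; the
emergent behavior of interest is the nematic, vertically columnar ordering of
the bulk population and its destabilization at small division lengths.

Intracellular species live in ``ABMState.species`` as concentrations (amount
per unit length), so the proportional-split rule at division is equivalent to
daughters inheriting the mother's concentration unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import W_CELL, relax_kernel

__all__ = [
    "StrainParams",
    "TrapGeometry",
    "MechParams",
    "ABMParams",
    "ABMState",
    "grow",
    "maybe_divide",
    "relax_mechanics",
    "remove_exited",
    "step_abm",
    "induce_length_reduction",
    "simulate_abm",
    "seed_cells",
]

N_SPECIES = 3  # C4HSL, C14HSL, LacI concentrations


@dataclass(frozen=True)
class StrainParams:
    """Per-strain morphology parameters.

    lbar_d : mean division length, um.
    a : division-length reduction factor applied on induction (1 = none).
    doubling_time : exponential length-doubling time, min.
    """

    lbar_d: float = 4.2
    a: float = 0.6
    doubling_time: float = 20.0
    name: str = "strain"

    def __post_init__(self) -> None:
        if self.lbar_d <= W_CELL:
            raise ValueError("mean division length must exceed the cell width")
        if not (0.0 < self.a <= 1.0):
            raise ValueError("reduction factor a must lie in (0, 1]")


@dataclass(frozen=True)
class TrapGeometry:
    """Open rectangular trapping region, origin at the lower-left corner."""

    width: float = 100.0
    height: float = 20.0

    def contains(self, x, y):
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass(frozen=True)
class MechParams:
    """Contact-mechanics constants (documented stand-ins, all configurable)."""

    k_rep: float = 40.0  # contact stiffness, force/um of overlap
    zeta: float = 1.0  # translational drag per unit length
    zeta_rot: float = 3.0  # rotational drag per unit length cubed
    tol: float = 0.05  # residual overlap tolerance, um
    max_iter: int = 120  # relaxation iteration cap per step
    step_cap: float = 0.05  # largest per-iteration displacement, um


@dataclass(frozen=True)
class ABMParams:
    geometry: TrapGeometry = TrapGeometry()
    strains: tuple[StrainParams, StrainParams] = (
        StrainParams(name="blue"),
        StrainParams(name="orange"),
    )
    mech: MechParams = MechParams()
    dt: float = 0.02  # min
    division_noise: float = 0.02  # daughter angle jitter, rad
    induction_time: float | None = None  # min; reduce strain 1 (orange) lbar_d
    induced_strain: int = 1
    hard_cap: int = 20000  # runaway guard


@dataclass
class ABMState:
    """Struct-of-arrays population state."""

    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray  # radians from horizontal, kept in [0, pi)
    length: np.ndarray  # pole-to-pole, um
    birth_length: np.ndarray
    strain: np.ndarray  # int8
    species: np.ndarray  # (n, N_SPECIES) concentrations
    f_axial: np.ndarray
    reduced: np.ndarray  # bool, per-cell division-length reduction flag
    time: float = 0.0

    @property
    def n(self) -> int:
        return self.x.size

    def half_length(self) -> np.ndarray:
        return np.maximum(0.0, (self.length - W_CELL) / 2.0)

    def select(self, mask: np.ndarray) -> "ABMState":
        return ABMState(
            self.x[mask], self.y[mask], self.phi[mask], self.length[mask],
            self.birth_length[mask], self.strain[mask], self.species[mask],
            self.f_axial[mask], self.reduced[mask], self.time,
        )


def _empty_state() -> ABMState:
    z = np.empty(0)
    return ABMState(
        z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
        np.empty(0, np.int8), np.empty((0, N_SPECIES)), z.copy(),
        np.empty(0, bool),
    )


def seed_cells(
    params: ABMParams,
    n_cells: int = 64,
    mode: str = "random-mixed",
    rng: np.random.Generator | None = None,
    max_tries: int = 2000,
) -> ABMState:
    """Seed the trap with non-overlapping cells.

    mode: "random-mixed" (uniform positions, strain by fair coin),
    "separated" (blue left half, orange right half), or "single" (all blue).
    Initial lengths are uniform on [0.5, 0.9] * lbar_d to stagger first
    divisions; placement rejects center distances below 1.2 um, with a bounded
    number of retries.
    """
    rng = np.random.default_rng() if rng is None else rng
    geo = params.geometry
    xs: list[float] = []
    ys: list[float] = []
    tries = 0
    while len(xs) < n_cells:
        if tries > max_tries * n_cells:
            raise RuntimeError("could not place seed cells without overlap")
        tries += 1
        cx = rng.uniform(2.0, geo.width - 2.0)
        cy = rng.uniform(1.0, geo.height - 1.0)
        if any((cx - a) ** 2 + (cy - b) ** 2 < 1.2**2 for a, b in zip(xs, ys)):
            continue
        xs.append(cx)
        ys.append(cy)
    x = np.array(xs)
    y = np.array(ys)
    if mode == "single":
        strain = np.zeros(n_cells, np.int8)
    elif mode == "random-mixed":
        strain = rng.integers(0, 2, n_cells).astype(np.int8)
    elif mode == "separated":
        strain = np.where(x < geo.width / 2.0, 0, 1).astype(np.int8)
    else:
        raise ValueError(f"unknown seeding mode {mode!r}")
    lbar = np.array([params.strains[int(s)].lbar_d for s in strain])
    length = rng.uniform(0.5, 0.9, n_cells) * lbar
    return ABMState(
        x=x, y=y,
        phi=rng.uniform(0.0, np.pi, n_cells),
        length=length,
        birth_length=length / 2.0,
        strain=strain,
        species=np.zeros((n_cells, N_SPECIES)),
        f_axial=np.zeros(n_cells),
        reduced=np.zeros(n_cells, bool),
    )


def grow(state: ABMState, params: ABMParams, dt: float) -> ABMState:
    """Exponential length growth over dt minutes; width is constant."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    for k, sp in enumerate(params.strains):
        mask = state.strain == k
        state.length[mask] *= 2.0 ** (dt / sp.doubling_time)
    return state


def effective_lbar(state: ABMState, params: ABMParams) -> np.ndarray:
    """Per-cell effective mean division length (reduction flags applied)."""
    lbar = np.empty(state.n)
    for k, sp in enumerate(params.strains):
        mask = state.strain == k
        lbar[mask] = np.where(state.reduced[mask], sp.a * sp.lbar_d, sp.lbar_d)
    return lbar


def division_targets(state: ABMState, params: ABMParams) -> np.ndarray:
    """l_d = sqrt(2 l0) * sqrt(lbar_eff), recomputed from stored birth lengths."""
    return np.sqrt(2.0 * state.birth_length * effective_lbar(state, params))


def maybe_divide(
    state: ABMState, params: ABMParams, rng: np.random.Generator
) -> ABMState:
    """Divide every cell whose length has reached its division target.

    Daughters are placed end-to-end within the mother's footprint with birth
    lengths eps0*l and (1-eps0)*l, eps0 ~ U[0.45, 0.55]; each daughter angle
    gets a small symmetric jitter; intracellular concentrations are inherited
    (equivalently, amounts split in proportion to birth length).
    """
    targets = division_targets(state, params)
    ready = state.length >= targets
    if not ready.any():
        return state
    keep = state.select(~ready)
    mom = state.select(ready)
    m = mom.n
    eps0 = rng.uniform(0.45, 0.55, m)
    ux, uy = np.cos(mom.phi), np.sin(mom.phi)
    la = eps0 * mom.length
    lb = mom.length - la
    off_a = (la - mom.length) / 2.0  # signed axial offset of daughter A center
    off_b = (mom.length - lb) / 2.0
    parts = []
    for l_d, off in ((la, off_a), (lb, off_b)):
        parts.append(
            ABMState(
                x=mom.x + off * ux,
                y=mom.y + off * uy,
                phi=np.mod(mom.phi + rng.normal(0.0, params.division_noise, m), np.pi),
                length=l_d.copy(),
                birth_length=l_d.copy(),
                strain=mom.strain.copy(),
                species=mom.species.copy(),
                f_axial=np.zeros(m),
                reduced=mom.reduced.copy(),
                time=mom.time,
            )
        )
    return _concat([keep, parts[0], parts[1]], state.time)


def _concat(states: list[ABMState], time: float) -> ABMState:
    return ABMState(
        np.concatenate([s.x for s in states]),
        np.concatenate([s.y for s in states]),
        np.concatenate([s.phi for s in states]),
        np.concatenate([s.length for s in states]),
        np.concatenate([s.birth_length for s in states]),
        np.concatenate([s.strain for s in states]),
        np.concatenate([s.species for s in states]),
        np.concatenate([s.f_axial for s in states]),
        np.concatenate([s.reduced for s in states]),
        time,
    )


def relax_mechanics(state: ABMState, params: ABMParams) -> tuple[ABMState, dict]:
    """Quasi-static overdamped relaxation of cell overlaps.

    Updates centers, angles, and F_axial in place; returns the state plus a
    diagnostics dict with the residual overlap and iteration count (a residual
    above tolerance at the iteration cap is flagged, not fatal).
    """
    me = params.mech
    f_ax, max_ov, n_iter = relax_kernel(
        state.x, state.y, state.phi, state.length, state.half_length(),
        me.k_rep, me.zeta, me.zeta_rot, me.tol, me.max_iter, me.step_cap,
    )
    state.f_axial = f_ax
    state.phi = np.mod(state.phi, np.pi)
    info = {
        "max_overlap": float(max_ov),
        "iterations": int(n_iter),
        "converged": bool(max_ov < me.tol),
    }
    return state, info


def remove_exited(state: ABMState, params: ABMParams) -> ABMState:
    """Drop cells whose center lies outside the trap rectangle."""
    inside = params.geometry.contains(state.x, state.y)
    return state if inside.all() else state.select(inside)


def induce_length_reduction(state: ABMState, strain_id: int, a: float | None = None) -> ABMState:
    """Mark all live cells of a strain as division-length reduced.

    Division targets are recomputed from stored birth lengths on the next
    division check, so cells already past the reduced target divide then.
    """
    if strain_id not in (0, 1):
        raise ValueError(f"unknown strain id {strain_id}")
    state.reduced |= state.strain == strain_id
    return state


def step_abm(
    state: ABMState,
    params: ABMParams,
    rng: np.random.Generator,
    dt: float | None = None,
    qs_update=None,
) -> tuple[ABMState, dict]:
    """One update cycle: grow, divide, relax, remove, then (optionally) QS.

    ``qs_update(state) -> state`` is the signaling hook evaluated last; it may
    set per-cell ``reduced`` flags for the next division check.
    """
    dt = params.dt if dt is None else dt
    state = grow(state, params, dt)
    state = maybe_divide(state, params, rng)
    if state.n > params.hard_cap:
        raise RuntimeError(f"population {state.n} exceeded hard cap (runaway)")
    state, info = relax_mechanics(state, params)
    state = remove_exited(state, params)
    state.time += dt
    if (
        params.induction_time is not None
        and state.time >= params.induction_time
    ):
        induce_length_reduction(state, params.induced_strain)
    if qs_update is not None:
        state = qs_update(state)
    return state, info


def snapshot(state: ABMState) -> dict:
    """Plain-dict snapshot consumed by the analysis module."""
    return {
        "t": state.time,
        "x": state.x.copy(),
        "y": state.y.copy(),
        "phi": state.phi.copy(),
        "length": state.length.copy(),
        "strain": state.strain.copy(),
        "F_axial": state.f_axial.copy(),
        "reduced": state.reduced.copy(),
    }


def simulate_abm(
    params: ABMParams,
    n_seed: int = 64,
    seeding: str = "random-mixed",
    t_end: float = 600.0,
    sample_interval: float = 10.0,
    seed: int | np.random.Generator = 0,
    qs_update=None,
    dt: float | None = None,
) -> list[dict]:
    """Run the ABM and return snapshots every ``sample_interval`` minutes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = seed_cells(params, n_seed, seeding, rng)
    dt = params.dt if dt is None else dt
    snaps = [snapshot(state)]
    next_sample = sample_interval
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        state, _ = step_abm(state, params, rng, dt, qs_update)
        if state.time >= next_sample - 1e-9:
            snaps.append(snapshot(state))
            next_sample += sample_interval
    return snaps
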