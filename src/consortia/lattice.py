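"""Stochastic lattice model (LM) of a two-strain monolayer trap.

The rectangular microfluidic trap is reduced to an M x N lattice in which every
site always holds exactly one cell carrying a strain identity (blue/orange) and
an orientation (vertical/horizontal).  Cell size is not represented; instead a
per-strain rotation probability ``p_rot`` acts as a proxy for cell length
(shorter cells rotate more).  Cells divide at location-dependent directional
rates

    v+(i) = lam * exp(-kappa*(M - i))      v-(i) = lam * exp(-kappa*(i - 1))
    h+(j) = lam * exp(-kappa*(N - j))      h-(j) = lam * exp(-kappa*(j - 1))

(1-based row i counted from the bottom, column j from the left), so division is
fastest near the open boundary a cell grows toward; ``kappa`` sets how strongly
the intervening population damps growth.  A vertical cell divides up or down, a
horizontal cell left or right.  On division the in-place daughter keeps the
mother's site and orientation; the displacing daughter occupies the adjacent
site in the growth direction, pushing the whole half-row/column one site toward
the boundary; the cell pushed past the boundary is removed, so the lattice
stays full.  The displacing daughter flips orientation with a probability
averaged over the mother and her Moore neighborhood, which couples a cell's
rotational freedom to the morphology of its neighbors.

Events are simulated exactly with a Gillespie algorithm.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "V",
    "H",
    "BLUE",
    "ORANGE",
    "LMParams",
    "LatticeState",
    "DivisionEvent",
    "growth_rates",
    "effective_rotation_probability",
    "apply_division",
    "gillespie_step",
    "simulate_lm",
    "ensemble_fractions",
    "horizontal_growth_propensity",
    "make_lattice",
]

V, H = 0, 1  # orientation codes
BLUE, ORANGE = 0, 1  # strain codes

Rates = namedtuple("Rates", ["v_plus", "v_minus", "h_plus", "h_minus"])


@dataclass(frozen=True)
class LMParams:
    """Lattice-model parameters.

    lam is the per-cell base division rate; the default of 20 makes one model
    time unit span roughly two dozen generations, so the standard band-forming
    transient [0, 1] matches the agent-based model's multi-generation
    stabilization period (single-strain vertical bands must be in place before
    rotation probabilities are switched, or the rotation advantage cannot
    act).  kappa >= 0 is the growth damping; the default 0.035 keeps interior
    horizontal division rates damped but non-negligible on the default
    20 x 100 lattice (exp(-kappa*N/2) ~ 0.17), which the rotation-driven
    invasion and forcing mechanisms require.  p_rot/p_rot_post are
    (blue, orange) rotation probabilities before/after ``induction_time``.
    """

    M: int = 20
    N: int = 100
    lam: float = 20.0
    kappa: float = 0.035
    p_rot: tuple[float, float] = (0.0, 0.0)
    p_rot_post: tuple[float, float] | None = None
    induction_time: float = 1.0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.lam <= 0:
            raise ValueError("base growth rate lam must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        for pair in (self.p_rot, self.p_rot_post or (0, 0)):
            for p in pair:
                if not (0.0 <= p <= 1.0):
                    raise ValueError("rotation probabilities must lie in [0, 1]")

    def rotation_probs(self, time: float) -> tuple[float, float]:
        """(blue, orange) rotation probabilities in force at model time ``time``."""
        if self.p_rot_post is not None and time >= self.induction_time:
            return self.p_rot_post
        return self.p_rot

    # Directional-rate tables, 0-based internally (row 0 = bottom).
    def rate_tables(self):
        i = np.arange(self.M)
        j = np.arange(self.N)
        vplus = self.lam * np.exp(-self.kappa * (self.M - 1 - i))
        vminus = self.lam * np.exp(-self.kappa * i)
        hplus = self.lam * np.exp(-self.kappa * (self.N - 1 - j))
        hminus = self.lam * np.exp(-self.kappa * j)
        return vplus, vminus, hplus, hminus


@dataclass
class LatticeState:
    """Full lattice: per-site strain id and orientation, plus model time."""

    strain: np.ndarray  # (M, N) int8, BLUE/ORANGE
    orient: np.ndarray  # (M, N) int8, V/H
    time: float = 0.0

    def copy(self) -> "LatticeState":
        return LatticeState(self.strain.copy(), self.orient.copy(), self.time)

    @property
    def shape(self) -> tuple[int, int]:
        return self.strain.shape

    def fraction(self, strain: int = ORANGE) -> float:
        return float(np.mean(self.strain == strain))

    def horizontal_fraction(self) -> float:
        return float(np.mean(self.orient == H))


@dataclass(frozen=True)
class DivisionEvent:
    site: tuple[int, int]  # (row, col), 0-based, row 0 = bottom
    direction: str  # "up" | "down" | "left" | "right"
    daughter_orientation: int  # V or H
    waiting_time: float


def make_lattice(
    params: LMParams,
    seeding: str = "random-mixed",
    rng: np.random.Generator | None = None,
    orientation: str = "random",
    strain: int = BLUE,
) -> LatticeState:
    """Fully occupied initial lattice.

    seeding: "single" (all ``strain``), "random-mixed" (fair coin per site) or
    "separated" (orange left half, blue right half).  Orientations are uniform
    random unless ``orientation="all-V"``.
    """
    rng = np.random.default_rng() if rng is None else rng
    M, N = params.M, params.N
    if seeding == "single":
        s = np.full((M, N), strain, dtype=np.int8)
    elif seeding == "random-mixed":
        s = rng.integers(0, 2, size=(M, N)).astype(np.int8)
    elif seeding == "separated":
        s = np.full((M, N), BLUE, dtype=np.int8)
        s[:, : N // 2] = ORANGE
    else:
        raise ValueError(f"unknown seeding mode {seeding!r}")
    if orientation == "all-V":
        o = np.full((M, N), V, dtype=np.int8)
    elif orientation == "random":
        o = rng.integers(0, 2, size=(M, N)).astype(np.int8)
    else:
        raise ValueError(f"unknown orientation init {orientation!r}")
    return LatticeState(s, o, 0.0)


def growth_rates(i: int, j: int, orientation: int, params: LMParams) -> Rates:
    """Directional division rates at 1-based site (i, j); row 1 is the bottom
    row, column 1 the leftmost column.

    All four directional rates are returned; a vertical cell exposes only
    (v_plus, v_minus), a horizontal cell only (h_plus, h_minus).
    """
    if not (1 <= i <= params.M and 1 <= j <= params.N):
        raise ValueError(f"site ({i}, {j}) outside {params.M} x {params.N} lattice")
    if orientation not in (V, H):
        raise ValueError("orientation must be V or H")
    lam, k = params.lam, params.kappa
    return Rates(
        v_plus=lam * np.exp(-k * (params.M - i)),
        v_minus=lam * np.exp(-k * (i - 1)),
        h_plus=lam * np.exp(-k * (params.N - j)),
        h_minus=lam * np.exp(-k * (j - 1)),
    )


def effective_rotation_probability(
    state: LatticeState, site: tuple[int, int], params: LMParams
) -> float:
    """Rotation probability of the displacing daughter at ``site`` (0-based).

    The arithmetic mean of the intrinsic p_rot of the mother cell and of every
    existing cell in her Moore neighborhood (8 in the interior, fewer at the
    boundary).  When all existing neighbors share the mother's strain this is
    exactly the strain's own p_rot.
    """
    i, j = site
    M, N = state.shape
    if not (0 <= i < M and 0 <= j < N):
        raise ValueError(f"site {site} outside lattice")
    pb, po = params.rotation_probs(state.time)
    block = state.strain[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
    probs = np.where(block == ORANGE, po, pb)
    return float(np.mean(probs))


_DIR = {"up": (1, 0), "down": (-1, 0), "right": (0, 1), "left": (0, -1)}


def apply_division(state: LatticeState, event: DivisionEvent) -> LatticeState:
    """Apply a division event in place (and return the state).

    The in-place daughter keeps the mother's site and orientation.  The
    displacing daughter takes the adjacent site in the division direction with
    ``event.daughter_orientation``; every cell from that site to the boundary
    shifts one site outward and the cell pushed past the boundary is removed.
    A mother already at the boundary in the division direction loses the
    displacing daughter immediately (nothing shifts).
    """
    i, j = event.site
    M, N = state.shape
    di, dj = _DIR[event.direction]
    vertical = di != 0
    mother_orient = state.orient[i, j]
    if vertical and mother_orient != V or (not vertical and mother_orient != H):
        raise ValueError("division direction inconsistent with mother orientation")
    ti, tj = i + di, j + dj
    state.time += event.waiting_time
    if not (0 <= ti < M and 0 <= tj < N):
        return state  # displacing daughter born past the boundary: removed
    if event.direction == "up":
        state.strain[ti + 1 :, j] = state.strain[ti:-1, j]
        state.orient[ti + 1 :, j] = state.orient[ti:-1, j]
    elif event.direction == "down":
        state.strain[:ti, j] = state.strain[1 : ti + 1, j]
        state.orient[:ti, j] = state.orient[1 : ti + 1, j]
    elif event.direction == "right":
        state.strain[i, tj + 1 :] = state.strain[i, tj:-1]
        state.orient[i, tj + 1 :] = state.orient[i, tj:-1]
    else:  # left
        state.strain[i, :tj] = state.strain[i, 1 : tj + 1]
        state.orient[i, :tj] = state.orient[i, 1 : tj + 1]
    state.strain[ti, tj] = state.strain[i, j]
    state.orient[ti, tj] = event.daughter_orientation
    return state


class _RateCache:
    """Per-cell total division rates maintained across events."""

    def __init__(self, params: LMParams):
        vp, vm, hp, hm = params.rate_tables()
        self.row_rate = vp + vm  # total rate of a V cell in row i
        self.col_rate = hp + hm  # total rate of an H cell in column j
        self.vp, self.vm, self.hp, self.hm = vp, vm, hp, hm

    def full(self, orient: np.ndarray) -> np.ndarray:
        return np.where(
            orient == V, self.row_rate[:, None], self.col_rate[None, :]
        )


def gillespie_step(
    state: LatticeState,
    params: LMParams,
    rng: np.random.Generator,
    cache: _RateCache | None = None,
    cell_rate: np.ndarray | None = None,
) -> tuple[DivisionEvent, float]:
    """Draw the next division event and its waiting time (state untouched).

    The waiting time is exponential with rate R = sum over cells of their two
    exposed directional rates; the event is chosen proportionally to its rate;
    the displacing daughter's orientation is flipped with the neighbor-averaged
    rotation probability of the mother's site.
    """
    cache = cache or _RateCache(params)
    if cell_rate is None:
        cell_rate = cache.full(state.orient)
    flat = cell_rate.ravel()
    cum = np.cumsum(flat)
    R = cum[-1]
    if R <= 0:
        raise RuntimeError("total event rate is non-positive on a full lattice")
    dt = rng.exponential(1.0 / R)
    k = int(np.searchsorted(cum, rng.random() * R, side="right"))
    M, N = state.shape
    i, j = divmod(k, N)
    if state.orient[i, j] == V:
        p_up = cache.vp[i] / (cache.vp[i] + cache.vm[i])
        direction = "up" if rng.random() < p_up else "down"
    else:
        p_right = cache.hp[j] / (cache.hp[j] + cache.hm[j])
        direction = "right" if rng.random() < p_right else "left"
    p_eff = effective_rotation_probability(state, (i, j), params)
    mother = int(state.orient[i, j])
    daughter = 1 - mother if rng.random() < p_eff else mother
    return DivisionEvent((i, j), direction, daughter, dt), dt


def _refresh_rates(cache: _RateCache, state: LatticeState, cell_rate, event) -> None:
    """Recompute the cached rates of the row/column touched by an event."""
    i, j = event.site
    if event.direction in ("up", "down"):
        col = state.orient[:, j]
        cell_rate[:, j] = np.where(col == V, cache.row_rate, cache.col_rate[j])
    else:
        row = state.orient[i, :]
        cell_rate[i, :] = np.where(row == V, cache.row_rate[i], cache.col_rate)


@njit(cache=True)
def _lm_kernel(
    strain, orient, vp, vm, hp, hm,
    p_pre_b, p_pre_o, p_post_b, p_post_o, t_induct,
    t_end, sample_dt, seed, out_f_orange, out_f_h,
):
    """Event loop of the lattice model (same dynamics as the per-operation
    functions, compiled).  Fills the per-sample output arrays; returns the
    number of samples written (including t = 0)."""
    np.random.seed(seed)
    M, N = strain.shape
    row_rate = vp + vm
    col_rate = hp + hm
    cell_rate = np.empty((M, N))
    for i in range(M):
        for j in range(N):
            cell_rate[i, j] = row_rate[i] if orient[i, j] == 0 else col_rate[j]

    def _record(k):
        n_or = 0
        n_h = 0
        for i in range(M):
            for j in range(N):
                n_or += strain[i, j]
                n_h += orient[i, j]
        out_f_orange[k] = n_or / (M * N)
        out_f_h[k] = n_h / (M * N)

    _record(0)
    n_written = 1
    t = 0.0
    next_sample = sample_dt
    max_samples = out_f_orange.shape[0]
    while t < t_end:
        R = 0.0
        for i in range(M):
            for j in range(N):
                R += cell_rate[i, j]
        dt = np.random.exponential(1.0 / R)
        t_new = t + dt
        lim = t_new if t_new < t_end else t_end
        while next_sample <= lim + 1e-12 and n_written < max_samples:
            _record(n_written)
            n_written += 1
            next_sample += sample_dt
        if t_new > t_end:
            break
        # select the dividing cell proportionally to its total rate
        target = np.random.random() * R
        acc = 0.0
        ci = M - 1
        cj = N - 1
        done = False
        for i in range(M):
            if done:
                break
            for j in range(N):
                acc += cell_rate[i, j]
                if acc >= target:
                    ci = i
                    cj = j
                    done = True
                    break
        # direction within the two exposed rates
        if orient[ci, cj] == 0:  # V
            up = np.random.random() < vp[ci] / (vp[ci] + vm[ci])
        else:
            up = np.random.random() < hp[cj] / (hp[cj] + hm[cj])  # "up"=right
        # neighbor-averaged rotation probability at the mother's site
        if t < t_induct:
            pb, po = p_pre_b, p_pre_o
        else:
            pb, po = p_post_b, p_post_o
        psum = 0.0
        cnt = 0
        for di in range(-1, 2):
            for dj in range(-1, 2):
                ii = ci + di
                jj = cj + dj
                if 0 <= ii < M and 0 <= jj < N:
                    psum += po if strain[ii, jj] == 1 else pb
                    cnt += 1
        p_eff = psum / cnt
        mother_orient = orient[ci, cj]
        daughter = 1 - mother_orient if np.random.random() < p_eff else mother_orient
        mother_strain = strain[ci, cj]
        # shift and insert
        if mother_orient == 0:  # vertical division
            if up:
                ti = ci + 1
                if ti < M:
                    for i in range(M - 1, ti, -1):
                        strain[i, cj] = strain[i - 1, cj]
                        orient[i, cj] = orient[i - 1, cj]
                        cell_rate[i, cj] = (
                            row_rate[i] if orient[i, cj] == 0 else col_rate[cj]
                        )
                    strain[ti, cj] = mother_strain
                    orient[ti, cj] = daughter
                    cell_rate[ti, cj] = (
                        row_rate[ti] if daughter == 0 else col_rate[cj]
                    )
            else:
                ti = ci - 1
                if ti >= 0:
                    for i in range(0, ti):
                        strain[i, cj] = strain[i + 1, cj]
                        orient[i, cj] = orient[i + 1, cj]
                        cell_rate[i, cj] = (
                            row_rate[i] if orient[i, cj] == 0 else col_rate[cj]
                        )
                    strain[ti, cj] = mother_strain
                    orient[ti, cj] = daughter
                    cell_rate[ti, cj] = (
                        row_rate[ti] if daughter == 0 else col_rate[cj]
                    )
        else:  # horizontal division; up == rightward
            if up:
                tj = cj + 1
                if tj < N:
                    for j in range(N - 1, tj, -1):
                        strain[ci, j] = strain[ci, j - 1]
                        orient[ci, j] = orient[ci, j - 1]
                        cell_rate[ci, j] = (
                            row_rate[ci] if orient[ci, j] == 0 else col_rate[j]
                        )
                    strain[ci, tj] = mother_strain
                    orient[ci, tj] = daughter
                    cell_rate[ci, tj] = (
                        row_rate[ci] if daughter == 0 else col_rate[tj]
                    )
            else:
                tj = cj - 1
                if tj >= 0:
                    for j in range(0, tj):
                        strain[ci, j] = strain[ci, j + 1]
                        orient[ci, j] = orient[ci, j + 1]
                        cell_rate[ci, j] = (
                            row_rate[ci] if orient[ci, j] == 0 else col_rate[j]
                        )
                    strain[ci, tj] = mother_strain
                    orient[ci, tj] = daughter
                    cell_rate[ci, tj] = (
                        row_rate[ci] if daughter == 0 else col_rate[tj]
                    )
        t = t_new
    return n_written


def simulate_lm(
    params: LMParams,
    seeding: str = "random-mixed",
    t_end: float = 3.0,
    sample_interval: float = 0.05,
    seed: int | np.random.Generator = 0,
    orientation: str = "random",
    strain: int = BLUE,
    store_grids: bool = False,
    engine: str = "compiled",
):
    """Run one lattice-model trajectory.

    Emits a pandas DataFrame of per-sample scalars (time, f_orange, f_H, q)
    sampled every ``sample_interval``; with ``store_grids`` the sampled
    (strain, orient) grids are returned as well (reference engine only).  When
    ``p_rot_post`` is set in ``params``, rotation probabilities change at
    ``params.induction_time``.

    ``engine="compiled"`` runs the numba event loop; ``engine="reference"``
    runs the per-operation Python path (identical dynamics, independent event
    loop, used for cross-checks and grid recording).
    """
    if params.p_rot_post is not None and t_end < params.induction_time:
        raise ValueError("t_end precedes the induction time")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = make_lattice(params, seeding, rng, orientation, strain)
    if engine == "compiled":
        if store_grids:
            raise ValueError("grid recording requires engine='reference'")
        vp, vm, hp, hm = params.rate_tables()
        pb, po = params.p_rot
        if params.p_rot_post is not None:
            pb2, po2 = params.p_rot_post
            t_ind = params.induction_time
        else:
            pb2, po2 = pb, po
            t_ind = np.inf
        n_samples = int(np.floor(t_end / sample_interval + 1e-9)) + 1
        f_or = np.zeros(n_samples)
        f_h = np.zeros(n_samples)
        kseed = int(rng.integers(2**31))
        n = _lm_kernel(
            state.strain, state.orient, vp, vm, hp, hm,
            pb, po, pb2, po2, t_ind,
            t_end, sample_interval, kseed, f_or, f_h,
        )
        # pad any unwritten trailing samples (end-time coincidence) with last
        f_or[n:] = f_or[n - 1]
        f_h[n:] = f_h[n - 1]
        times = np.arange(n_samples) * sample_interval
        return pd.DataFrame(
            {
                "time": times,
                "f_orange": f_or,
                "f_H": f_h,
                "q": np.abs(2.0 * f_h - 1.0),
            }
        )
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")
    cache = _RateCache(params)
    cell_rate = cache.full(state.orient)

    def scalars(t):
        f_h = state.horizontal_fraction()
        return (t, state.fraction(ORANGE), f_h, abs(2.0 * f_h - 1.0))

    records = [scalars(0.0)]
    grids = [(0.0, state.strain.copy(), state.orient.copy())] if store_grids else None
    next_sample = sample_interval
    while state.time < t_end:
        event, dt = gillespie_step(state, params, rng, cache, cell_rate)
        t_new = state.time + dt
        while next_sample <= min(t_new, t_end) + 1e-12:
            records.append(scalars(next_sample))
            if store_grids:
                grids.append((next_sample, state.strain.copy(), state.orient.copy()))
            next_sample += sample_interval
        if t_new > t_end:
            state.time = t_end
            break
        apply_division(state, event)
        _refresh_rates(cache, state, cell_rate, event)
    df = pd.DataFrame(records, columns=["time", "f_orange", "f_H", "q"])
    return (df, grids) if store_grids else df


def ensemble_fractions(
    params: LMParams,
    seeding: str,
    n_replicates: int,
    t_end: float,
    sample_interval: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Ensemble of replicate runs: per-sample mean/sd of the orange fraction.

    Returns a DataFrame (time, mean, sd) plus one column per replicate.
    """
    root = np.random.default_rng(seed)
    cols = {}
    for r in range(n_replicates):
        df = simulate_lm(
            params,
            seeding,
            t_end=t_end,
            sample_interval=sample_interval,
            seed=np.random.default_rng(root.integers(2**31)),
        )
        cols[f"rep{r}"] = df["f_orange"].to_numpy()
        time = df["time"].to_numpy()
    out = pd.DataFrame(cols, index=pd.Index(time, name="time"))
    summary = pd.DataFrame(
        {"time": time, "mean": out.mean(axis=1).to_numpy(), "sd": out.std(axis=1).to_numpy()}
    )
    return pd.concat([summary, out.reset_index(drop=True)], axis=1)


def horizontal_growth_propensity(
    state: LatticeState, strain: int, params: LMParams
) -> float:
    """Mean horizontal growth propensity of a strain.

    (1/sigma_k) * sum over horizontally oriented cells of strain k of
    (h+(j) + h-(j)), where sigma_k counts all strain-k cells.  Describes the
    propensity of strain k to displace its competitor laterally.
    """
    sigma = int(np.sum(state.strain == strain))
    if sigma == 0:
        raise ValueError(f"strain {strain} absent from the lattice")
    _, _, hp, hm = params.rate_tables()
    mask = (state.strain == strain) & (state.orient == H)
    cols = np.nonzero(mask)[1]
    return float(np.sum(hp[cols] + hm[cols]) / sigma)
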