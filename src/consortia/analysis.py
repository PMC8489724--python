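"""Population statistics for trap simulations.

Nematic order parameter, region-wise ordering, kymographs of order and
horizontal force, strain-fraction time series, and the exponential
rate-parameter fits used to quantify strain displacement.

Angles are measured from horizontal in the lab frame and treated nematically
(phi and phi + pi are the same orientation), so all statistics are built from
cos(2*phi) and sin(2*phi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "order_parameter",
    "region_q",
    "kymograph",
    "strain_fraction_series",
    "fit_alpha",
    "alpha_vs_parameter",
    "FitResult",
]


def order_parameter(angles, weights=None) -> float:
    """Nematic order parameter q = sqrt(<cos 2phi>^2 + <sin 2phi>^2).

    q = 1 for perfect alignment, q = 0 for a fully disordered (uniform)
    orientation distribution.  For a two-orientation vertical/horizontal
    population this reduces to \\|2 f_H - 1\\| where f_H is the horizontal
    fraction.

    Parameters
    ----------
    angles : array-like of float
        Cell angles from horizontal, radians; nematic so any representative
        of phi mod pi is accepted.
    weights : array-like, optional
        Per-cell averaging weights (e.g. cell lengths).
    """
    phi = np.asarray(angles, dtype=float)
    if phi.size == 0:
        raise ValueError("order parameter undefined for an empty sample")
    c = np.average(np.cos(2.0 * phi), weights=weights)
    s = np.average(np.sin(2.0 * phi), weights=weights)
    return float(np.hypot(c, s))


def region_q(x, angles, regions: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Order parameter per named x-interval region of a snapshot.

    ``regions`` maps a name to an ``(x_lo, x_hi)`` interval; a cell belongs to
    a region when its center x-coordinate falls inside.  Empty regions map to
    ``nan`` (flagged, to be excluded from downstream averages).
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(angles, dtype=float)
    out: dict[str, float] = {}
    for name, (lo, hi) in regions.items():
        mask = (x >= lo) & (x < hi)
        out[name] = order_parameter(phi[mask]) if mask.any() else float("nan")
    return out


def default_regions(width: float) -> dict[str, tuple[float, float]]:
    """Bulk/edge analysis boxes for a trap of a given width.

    Edges are the outer 15% full-height strips on each side, bulk the central
    40% strip (15 um edges / 40 um bulk for the 100 um reference trap).
    """
    return {
        "bulk": (0.3 * width, 0.7 * width),
        "edge_left": (0.0, 0.15 * width),
        "edge_right": (0.85 * width, width),
    }


def kymograph(
    snapshots,
    statistic: str = "q",
    width: float | None = None,
    column_width: float = 1.0,
):
    """Column-resolved statistic over time: a 2D field indexed by (t, x).

    Each snapshot is a mapping or object with arrays ``x``, ``phi`` and, for
    ``statistic="F_x"``, ``F_axial``; cells are binned into ``column_width``
    wide columns by center coordinate.  Per column the statistic is either the
    nematic order parameter q of the member cells or the horizontally
    projected mean force F_x = (1/n) sum_k F_k cos(phi_k).  Because angles are
    nematic (phi and phi + pi identified) the projection uses \\|cos phi\\|,
    which is invariant under the identification; the axial expansion force F_k
    is an unsigned load.  Empty columns are NaN.

    Returns ``(times, x_centers, field)`` with ``field`` of shape
    (n_snapshots, n_columns).
    """
    if statistic not in ("q", "F_x"):
        raise ValueError(f"unknown kymograph statistic {statistic!r}")
    times = np.array([float(s["t"]) for s in snapshots])
    if width is None:
        width = max(float(np.max(s["x"])) for s in snapshots if len(s["x"]))
    edges = np.arange(0.0, width + column_width, column_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    field = np.full((len(snapshots), len(centers)), np.nan)
    for row, snap in enumerate(snapshots):
        x = np.asarray(snap["x"], dtype=float)
        phi = np.asarray(snap["phi"], dtype=float)
        idx = np.digitize(x, edges) - 1
        for col in range(len(centers)):
            sel = idx == col
            if not sel.any():
                continue
            if statistic == "q":
                field[row, col] = order_parameter(phi[sel])
            else:
                f = np.asarray(snap["F_axial"], dtype=float)[sel]
                field[row, col] = float(np.mean(f * np.abs(np.cos(phi[sel]))))
    return times, centers, field


def strain_fraction_series(snapshots, strain: int = 1):
    """Fraction of cells of ``strain`` per snapshot: arrays (t, fraction).

    The series ends at the first empty snapshot.
    """
    ts, fr = [], []
    for snap in snapshots:
        s = np.asarray(snap["strain"])
        if s.size == 0:
            break
        ts.append(float(snap["t"]))
        fr.append(float(np.mean(s == strain)))
    return np.array(ts), np.array(fr)


@dataclass(frozen=True)
class FitResult:
    """Exponential displacement-rate fit.

    alpha : fitted rate (1/time in the units of the input series).
    mode : "invasion" (f = 1 - 0.5 exp(-alpha (t - t0))) or
           "forcing"  (f = 0.5 exp(alpha (t - t0))).
    window : (t0, t_end) actually used for the fit.
    r_squared : coefficient of determination on the window.
    """

    alpha: float
    mode: str
    window: tuple[float, float]
    r_squared: float


def fit_alpha(
    t,
    fraction,
    mode: str = "invasion",
    t0: float = 0.0,
    cutoff: float = 0.95,
    forcing_window: float = 1.0,
) -> FitResult:
    """Least-squares exponential fit of a mean strain-fraction series.

    Invasion mode fits ``1 - 0.5 exp(-alpha (t - t0))`` from t0 until the
    series first reaches ``cutoff``; forcing mode fits
    ``0.5 exp(alpha (t - t0))`` on the fixed window [t0, t0 + forcing_window].
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(fraction, dtype=float)
    if mode == "invasion":
        hit = np.flatnonzero((t >= t0) & (y >= cutoff))
        t_end = t[hit[0]] if hit.size else t[-1]
        model = lambda tt, a: 1.0 - 0.5 * np.exp(-a * (tt - t0))  # noqa: E731
    elif mode == "forcing":
        t_end = t0 + forcing_window
        model = lambda tt, a: 0.5 * np.exp(a * (tt - t0))  # noqa: E731
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    sel = (t >= t0) & (t <= t_end)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 points in the fit window")
    tt, yy = t[sel], y[sel]
    # data-driven initial rate: invert the model at the window end so the
    # guess is on the right timescale whatever the time units
    span = max(tt[-1] - t0, 1e-9)
    y_end = float(np.clip(yy[-1], 1e-6, None))
    if mode == "invasion":
        inner = np.clip(2.0 * (1.0 - y_end), 1e-9, 1.0 - 1e-9)
        a0 = -np.log(inner) / span
    else:
        a0 = np.log(np.clip(2.0 * y_end, 1e-9, None)) / span
    if not np.isfinite(a0) or abs(a0) < 1e-12:
        a0 = 1.0 / span
    popt, _ = curve_fit(model, tt, yy, p0=[a0], maxfev=10000)
    resid = yy - model(tt, *popt)
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(float(popt[0]), mode, (float(t0), float(t_end)), r2)


def alpha_vs_parameter(values, alphas, mode: str = "invasion") -> dict:
    """Summarize the dependence of the fitted rate alpha on a swept parameter.

    Reports strict monotonicity direction, a linear regression, and (for
    invasion sweeps over the length-reduction factor a) an exponential fit
    alpha = A exp(-B a).  Needs at least 3 parameter values.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(alphas, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 parameter values")
    order = np.argsort(v)
    v, a = v[order], a[order]
    d = np.diff(a)
    if np.all(d > 0):
        mono = "increasing"
    elif np.all(d < 0):
        mono = "decreasing"
    else:
        mono = "non-monotone"
    lin = linregress(v, a)
    out = {
        "monotonic": mono,
        "linear_slope": float(lin.slope),
        "linear_r2": float(lin.rvalue**2),
    }
    if mode == "invasion" and np.all(a > 0):
        # log-linear fit of alpha = A exp(-B v)
        el = linregress(v, np.log(a))
        out["exp_prefactor"] = float(np.exp(el.intercept))
        out["exp_rate"] = float(-el.slope)
        out["exp_r2"] = float(el.rvalue**2)
    return out
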