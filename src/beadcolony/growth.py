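"""Growth-curve models for bead-confined colonies.

Three nested descriptions of colony growth are implemented:

1. **Boltzmann sigmoid** (empirical smoother)::

       A(T) = A2 + (A1 - A2) / (1 + exp((T - T0)/dT))

2. **Baranyi–Roberts monoculture model** (generalized logistic / Richards)::

       dA/dT = r·A·(1 - (A/A2)^γ)

   with closed-form solution

       A(T) = A2·[1 + ((A2/A1)^γ - 1)·exp(-r·γ·T)]^(-1/γ)

   where r is the initial per-capita growth rate (1/h), γ a dimensionless
   deceleration parameter (γ=1 recovers the logistic), A1 the initial and A2
   the final colony size.  Colony area is taken proportional to cell number.

3. **Two-strain Lotka–Volterra competition model**::

       dA_B/dT = r_B·A_B·(1 - A_B^γB/A2B^γB - c_Y·A_Y^γY/A2B^γB)
       dA_Y/dT = r_Y·A_Y·(1 - c_B·A_B^γB/A2Y^γY - A_Y^γY/A2Y^γY)

   c_Y is the effect of strain Y on strain B and vice versa.  Note the
   cross term divides the competitor's density (raised to the competitor's
   own γ) by the *focal* strain's capacity raised to the focal γ; this
   asymmetric normalization is kept deliberately, with
   ``normalization="competitor"`` available to divide by the competitor's
   own capacity instead.

Fitting follows a two-stage scheme: raw per-colony points are first smoothed
with the Boltzmann sigmoid, then the mechanistic model is fitted to the
smoothed curve (direct raw-point fitting is available via ``smooth=False``).
The co-culture fit holds all monoculture parameters fixed and estimates only
the two competition coefficients from the summed co-culture curve, then
decomposes the total into per-strain trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares


class FitError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    """A time series of colony size (area, μm²) or fluorescence intensity."""

    times: np.ndarray
    values: np.ndarray
    signal_kind: str = "size"
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be nonnegative")
        if self.signal_kind not in ("size", "intensity"):
            raise ValueError("signal_kind must be 'size' or 'intensity'")

    def window(self, start: Optional[float] = None, stop: Optional[float] = None
               ) -> "GrowthCurve":
        mask = np.ones_like(self.times, dtype=bool)
        if start is not None:
            mask &= self.times >= start
        if stop is not None:
            mask &= self.times <= stop
        return GrowthCurve(self.times[mask], self.values[mask],
                           self.signal_kind, self.label)


@dataclass(frozen=True)
class SigmoidFit:
    """Boltzmann sigmoid parameters plus fit diagnostics."""

    a1: float
    a2: float
    t0: float
    dt: float
    rmse: float = float("nan")
    success: bool = True
    degenerate: bool = False
    message: str = ""


@dataclass(frozen=True)
class MonocultureParams:
    """Baranyi–Roberts parameters: rate r (1/h), deceleration γ, sizes A1 < A2."""

    r: float
    gamma: float
    a1: float
    a2: float

    def __post_init__(self) -> None:
        if self.r <= 0 or self.gamma <= 0:
            raise ValueError("r and gamma must be positive")
        if not 0 < self.a1 < self.a2:
            raise ValueError(f"need 0 < A1 < A2, got A1={self.a1}, A2={self.a2}")


@dataclass(frozen=True)
class CompetitionParams:
    """Per-strain Baranyi–Roberts parameters plus competition coefficients.

    ``c_y`` is the coefficient appearing in strain B's equation (effect of Y
    on B) and ``c_b`` the one in strain Y's equation (effect of B on Y).
    """

    b: MonocultureParams
    y: MonocultureParams
    c_b: float = 0.0
    c_y: float = 0.0
    normalization: str = "focal"

    def __post_init__(self) -> None:
        if self.c_b < 0 or self.c_y < 0 or not np.isfinite(self.c_b) or not np.isfinite(self.c_y):
            raise ValueError("competition coefficients must be finite and >= 0")
        if self.normalization not in ("focal", "competitor"):
            raise ValueError("normalization must be 'focal' or 'competitor'")


@dataclass
class MonocultureFit:
    params: MonocultureParams
    rmse: float
    success: bool
    gamma_at_bound: bool = False
    boltzmann: Optional[SigmoidFit] = None
    ci: Optional[dict] = None


@dataclass
class CompetitionFit:
    params: CompetitionParams
    rmse: float
    identifiable: bool
    times: np.ndarray
    a_b: np.ndarray
    a_y: np.ndarray
    profile_c_b: np.ndarray = field(default_factory=lambda: np.empty(0))
    profile_c_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    profile_rmse: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def boltzmann_eval(fit: SigmoidFit, t):
    """Evaluate the Boltzmann sigmoid at times ``t``."""
    t = np.asarray(t, dtype=float)
    z = np.clip((t - fit.t0) / fit.dt, -500.0, 500.0)
    a = fit.a2 + (fit.a1 - fit.a2) / (1.0 + np.exp(z))
    return a if np.ndim(a) else float(a)


def baranyi_roberts_eval(params: MonocultureParams, t):
    """Closed-form Baranyi–Roberts solution A(T) with A(0) = A1."""
    t = np.asarray(t, dtype=float)
    g = params.gamma
    bracket = 1.0 + ((params.a2 / params.a1) ** g - 1.0) * np.exp(-params.r * g * t)
    if np.any(bracket <= 0):
        raise ValueError("closed form undefined: bracket nonpositive "
                         f"(params={params})")
    a = params.a2 * bracket ** (-1.0 / g)
    return a if np.ndim(a) else float(a)


def baranyi_roberts_rhs(params: MonocultureParams, a):
    """Growth rate dA/dT = r·A·(1 − (A/A2)^γ) at size ``a``."""
    a = np.asarray(a, dtype=float)
    da = params.r * a * (1.0 - (a / params.a2) ** params.gamma)
    return da if np.ndim(da) else float(da)


def lv_rhs(params: CompetitionParams, state):
    """Right-hand side of the two-strain competition ODE at ``state=(A_B, A_Y)``."""
    ab, ay = max(float(state[0]), 0.0), max(float(state[1]), 0.0)
    pb, py = params.b, params.y
    if params.normalization == "focal":
        denom_in_b = pb.a2 ** pb.gamma
        denom_in_y = py.a2 ** py.gamma
        cross_b = params.c_y * ay ** py.gamma / denom_in_b
        cross_y = params.c_b * ab ** pb.gamma / denom_in_y
    else:  # competitor-normalized variant
        cross_b = params.c_y * (ay / py.a2) ** py.gamma
        cross_y = params.c_b * (ab / pb.a2) ** pb.gamma
    dab = pb.r * ab * (1.0 - (ab / pb.a2) ** pb.gamma - cross_b)
    day = py.r * ay * (1.0 - cross_y - (ay / py.a2) ** py.gamma)
    return dab, day


def lv_integrate(params: CompetitionParams, t_grid, y0=None,
                 rtol: float = 1e-8, atol: Optional[float] = None):
    """Integrate the competition ODE and return (A_B, A_Y) on ``t_grid``.

    Integration starts at T=0 from ``y0`` (default: the monoculture initial
    sizes (A1_B, A1_Y)); ``t_grid`` must be nondecreasing and nonnegative.
    States are clipped at zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) < 0) or np.any(t_grid < 0):
        raise ValueError("t_grid must be 1-D, nondecreasing and nonnegative")
    if y0 is None:
        y0 = (params.b.a1, params.y.a1)
    if y0[0] < 0 or y0[1] < 0:
        raise ValueError("initial sizes must be nonnegative")
    if atol is None:
        atol = 1e-10 * max(params.b.a2, params.y.a2)

    def rhs(_t, y):
        return lv_rhs(params, y)

    t_end = float(t_grid[-1]) if t_grid.size else 0.0
    sol = solve_ivp(rhs, (0.0, max(t_end, 1e-12)), np.asarray(y0, float),
                    t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"competition ODE integration failed: {sol.message}")
    ab = np.maximum(sol.y[0], 0.0)
    ay = np.maximum(sol.y[1], 0.0)
    return ab, ay


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _best_least_squares(residual, starts, bounds):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            res = least_squares(residual, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if res.x is not None and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("all optimizer starts failed")
    return best


def fit_boltzmann(curve: GrowthCurve, fit_start: Optional[float] = None,
                  seed: int = 0, n_starts: int = 5) -> SigmoidFit:
    """Bounded least-squares fit of the Boltzmann sigmoid.

    Requires at least 5 points in the fitting window.  A flat input curve is
    returned as a degenerate fit (A1 ≈ A2) rather than silent garbage; true
    optimizer failure raises :class:`FitError`.
    """
    if fit_start is not None:
        curve = curve.window(start=fit_start)
    t, y = curve.times, curve.values
    if t.size < 5:
        raise FitError(f"need >= 5 points to fit the sigmoid, got {t.size}")
    span = float(t[-1] - t[0])
    scale = float(np.ptp(y))
    if scale <= 1e-12 * max(1.0, float(np.abs(y).max())):
        m = float(y.mean())
        return SigmoidFit(a1=m, a2=m, t0=float(t.mean()), dt=span / 10.0,
                          rmse=float(y.std()), degenerate=True,
                          message="flat curve: A1 == A2")

    def residual(x):
        return boltzmann_eval(SigmoidFit(*x), t) - y

    ymax = float(y.max())
    half = float(y.min()) + scale / 2.0
    t0_guess = float(np.interp(half, y, t)) if np.all(np.diff(y) >= 0) else float(t.mean())
    x0 = np.array([float(y[0]), ymax, t0_guess, span / 8.0])
    lower = np.array([0.0, 1e-12, t[0] - span, span * 1e-3])
    upper = np.array([2.0 * ymax + 1e-9, 10.0 * ymax + 1e-9, t[-1] + span, 2.0 * span])

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        jit = x0 * np.exp(rng.normal(0.0, 0.3, size=4))
        jit[2] = x0[2] + rng.normal(0.0, span / 5.0)
        starts.append(jit)
    best = _best_least_squares(residual, starts, (lower, upper))
    a1, a2, t0, dt = best.x
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    degenerate = abs(a2 - a1) < 1e-6 * max(abs(a2), 1.0)
    return SigmoidFit(a1=float(a1), a2=float(a2), t0=float(t0), dt=float(dt),
                      rmse=rmse, success=bool(best.success or best.cost < np.inf),
                      degenerate=degenerate)


def smooth_curve(curve: GrowthCurve, n: int = 30,
                 fit_start: Optional[float] = None, seed: int = 0) -> GrowthCurve:
    """Boltzmann-smoothed version of a noisy curve on a dense time grid.

    This is the first stage of the study's two-stage scheme; fitting the
    mechanistic models to the smoothed curve strongly reduces the impact of
    per-point measurement noise on the recovered competition coefficients.
    """
    if fit_start is not None:
        curve = curve.window(start=fit_start)
    fit = fit_boltzmann(curve, seed=seed)
    t = np.linspace(curve.times[0], curve.times[-1], n)
    return GrowthCurve(t, np.asarray(boltzmann_eval(fit, t)),
                       curve.signal_kind, curve.label)


def fit_monoculture(curve: GrowthCurve, smooth: bool = True,
                    fit_start: Optional[float] = None, seed: int = 0,
                    n_starts: int = 5, n_smooth: int = 60) -> MonocultureFit:
    """Fit the Baranyi–Roberts model to a monoculture growth curve.

    With ``smooth=True`` (default) the raw points are first smoothed with the
    Boltzmann sigmoid and the mechanistic model is fitted to the smoothed
    curve on a dense grid; ``smooth=False`` fits the closed form directly to
    the raw points.  γ pinned at a bound is flagged.
    """
    if fit_start is not None:
        curve = curve.window(start=fit_start)
    if curve.times.size < 5:
        raise FitError(f"insufficient data: {curve.times.size} points (need >= 5)")

    boltz: Optional[SigmoidFit] = None
    if smooth:
        boltz = fit_boltzmann(curve, seed=seed)
        t = np.linspace(curve.times[0], curve.times[-1], n_smooth)
        y = np.asarray(boltzmann_eval(boltz, t))
    else:
        t, y = curve.times, curve.values

    ymax = float(y.max())
    if ymax <= 0 or float(np.ptp(y)) <= 1e-12 * max(1.0, ymax):
        raise FitError("cannot fit growth model to a flat or zero curve")

    gamma_lo, gamma_hi = 0.05, 20.0

    def residual(x):
        r, g, a1, da = x
        p = MonocultureParams(r=r, gamma=g, a1=a1, a2=a1 + da)
        return baranyi_roberts_eval(p, t) - y

    a1_guess = max(float(y[0]), 1e-9 * ymax)
    x0 = np.array([0.5, 1.0, a1_guess, max(ymax - a1_guess, 1e-6 * ymax)])
    lower = np.array([1e-3, gamma_lo, 1e-12, 1e-9 * ymax])
    upper = np.array([50.0, gamma_hi, 2.0 * ymax, 20.0 * ymax])

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        starts.append(x0 * np.exp(rng.normal(0.0, 0.3, size=4)))
    best = _best_least_squares(residual, starts, (lower, upper))
    r, g, a1, da = best.x
    params = MonocultureParams(r=float(r), gamma=float(g), a1=float(a1),
                               a2=float(a1 + da))
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    at_bound = bool(g <= gamma_lo * 1.01 or g >= gamma_hi * 0.99)
    return MonocultureFit(params=params, rmse=rmse, success=True,
                          gamma_at_bound=at_bound, boltzmann=boltz)


def bootstrap_monoculture_ci(curve: GrowthCurve, fit: MonocultureFit,
                             n_boot: int = 200, seed: int = 0,
                             level: float = 0.95) -> dict:
    """Residual-bootstrap confidence intervals for (r, γ, A1, A2).

    Resamples the raw-point residuals of the fitted closed form, refits from
    the point estimate, and returns per-parameter percentile intervals.
    """
    t, y = curve.times, curve.values
    yhat = np.asarray(baranyi_roberts_eval(fit.params, t))
    resid = y - yhat
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y_star = np.maximum(yhat + rng.choice(resid, size=resid.size, replace=True), 0.0)
        try:
            bfit = fit_monoculture(GrowthCurve(t, y_star, curve.signal_kind),
                                   smooth=False, seed=int(rng.integers(2**31)),
                                   n_starts=2)
        except (FitError, ValueError):
            continue
        p = bfit.params
        draws.append([p.r, p.gamma, p.a1, p.a2])
    if not draws:
        raise FitError("bootstrap failed: no successful refits")
    draws = np.asarray(draws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    names = ("r", "gamma", "a1", "a2")
    return {n: (float(lo[i]), float(hi[i])) for i, n in enumerate(names)}


def fit_competition(total_curve: GrowthCurve, mono_b: MonocultureParams,
                    mono_y: MonocultureParams, seed: int = 0,
                    normalization: str = "focal",
                    c_max: float = 10.0, profile_max: float = 2.0,
                    profile_n: int = 9, rtol: float = 1e-7) -> CompetitionFit:
    """Estimate the competition coefficients from the summed co-culture curve.

    All per-strain parameters are held fixed at their monoculture values; only
    (c_B, c_Y) ≥ 0 are estimated by bounded least squares between the observed
    total A_B + A_Y and the integrated competition model.  Returns the fitted
    coefficients, the decomposed per-strain trajectories on the curve's time
    grid, the fit RMSE, and a practical-identifiability diagnostic: the RMSE
    profile over a (c_B, c_Y) grid.  When the near-optimal set of that profile
    forms a ridge (e.g. for identical strains only c_B + c_Y is identified),
    ``identifiable`` is False.
    """
    t, y = total_curve.times, total_curve.values
    if t.size < 3:
        raise FitError("need >= 3 total-curve points to fit competition coefficients")

    def model_total(c_b, c_y, grid):
        params = CompetitionParams(b=mono_b, y=mono_y, c_b=c_b, c_y=c_y,
                                   normalization=normalization)
        ab, ay = lv_integrate(params, grid, rtol=rtol)
        return ab + ay, ab, ay

    def residual(x):
        tot, _, _ = model_total(x[0], x[1], t)
        return tot - y

    starts = [np.array(s) for s in
              ((0.5, 0.5), (0.05, 0.05), (1.5, 0.3), (0.3, 1.5), (1.0, 1.0))]
    rng = np.random.default_rng(seed)
    starts.append(rng.uniform(0.0, 2.0, size=2))
    bounds = (np.zeros(2), np.full(2, c_max))
    best = _best_least_squares(residual, starts, bounds)
    c_b, c_y = (float(v) for v in best.x)
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))

    # identifiability profile on a coarse grid (reported for inspection)
    grid = np.linspace(0.0, profile_max, profile_n)
    prof = np.empty((profile_n, profile_n))
    for i, gb in enumerate(grid):
        for j, gy in enumerate(grid):
            tot, _, _ = model_total(gb, gy, t)
            prof[i, j] = np.sqrt(np.mean((tot - y) ** 2))

    # practical identifiability: curvature of the cost around the optimum.
    # For identical strains the total curve is invariant to first order under
    # (c_B, c_Y) -> (c_B + ε, c_Y − ε), so the cost valley is a ridge: the
    # sensitivity along the soft direction collapses relative to the stiff one.
    def rmse_at(cb, cy):
        tot, _, _ = model_total(cb, cy, t)
        return float(np.sqrt(np.mean((tot - y) ** 2)))

    delta = 0.02
    sens = []
    for u in (np.array([1.0, 1.0]) / np.sqrt(2), np.array([1.0, -1.0]) / np.sqrt(2)):
        vals = []
        for sgn in (1.0, -1.0):
            c = np.clip(np.array([c_b, c_y]) + sgn * delta * u, 0.0, c_max)
            if np.allclose(c, [c_b, c_y]):
                continue
            vals.append(rmse_at(*c))
        sens.append(max(np.mean(vals) - rmse, 0.0) if vals else 0.0)
    s_max = max(sens)
    identifiable = bool(s_max > 0 and min(sens) / s_max > 0.05)

    tot, ab, ay = model_total(c_b, c_y, t)
    params = CompetitionParams(b=mono_b, y=mono_y, c_b=c_b, c_y=c_y,
                               normalization=normalization)
    return CompetitionFit(params=params, rmse=rmse, identifiable=identifiable,
                          times=t.copy(), a_b=ab, a_y=ay,
                          profile_c_b=grid, profile_c_y=grid, profile_rmse=prof)


# ---------------------------------------------------------------------------
# curve extraction from measurement tables
# ---------------------------------------------------------------------------

def bead_condition_ids(table):
    """Map bead_id -> set of strains present in that bead."""
    return table.groupby("bead_id")["strain"].agg(lambda s: frozenset(s))


def growth_curve_from_table(table, strain: str, signal: str = "size",
                            condition: str = "all", aggregate: str = "mean",
                            label: Optional[str] = None) -> GrowthCurve:
    """Aggregate per-colony measurements into a population growth curve.

    ``condition`` selects beads: "all", "mono" (beads containing only the
    requested strain) or "co" (beads containing both strains).  ``aggregate``
    is "mean" or "median" across colonies at each time point.
    """
    if signal not in ("size", "intensity"):
        raise ValueError("signal must be 'size' or 'intensity'")
    col = "area_um2" if signal == "size" else "intensity_au"
    sub = table[table["strain"] == strain]
    if condition != "all":
        strains_per_bead = bead_condition_ids(table)
        if condition == "mono":
            keep = strains_per_bead[strains_per_bead == frozenset({strain})].index
        elif condition == "co":
            keep = strains_per_bead[strains_per_bead == frozenset({"B", "Y"})].index
        else:
            raise ValueError("condition must be 'all', 'mono' or 'co'")
        sub = sub[sub["bead_id"].isin(keep)]
    if len(sub) == 0:
        raise ValueError(f"no rows for strain {strain!r} under condition {condition!r}")
    agg = sub.groupby("time_h")[col].mean() if aggregate == "mean" \
        else sub.groupby("time_h")[col].median()
    kind = "size" if signal == "size" else "intensity"
    return GrowthCurve(agg.index.to_numpy(float), agg.to_numpy(float),
                       signal_kind=kind, label=label or f"{strain}/{condition}")
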