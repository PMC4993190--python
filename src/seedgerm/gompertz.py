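"""Gompertz germination dynamics: curve, fitting, inversion and percentile rates.

Cumulative germination of a seed lot follows the Gompertz sigmoid

    G(t) = Gmax * exp[ -(b/c) * exp(-c*t) ]

with ``Gmax`` the final germination percentage (percent of sown seeds) and
``b``, ``c`` positive shape parameters (``c`` in 1/h). Germination rate for a
population percentile G (again percent of *sown* seeds, so a lot with
Gmax = 37 % never reaches its 40th percentile) is the reciprocal of the
closed-form inversion

    t(G) = -(1/c) * ln[ -(c/b) * ln(G/Gmax) ].
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .types import (
    Condition,
    GompertzFit,
    NoGerminationError,
    PercentileRate,
    PercentileUnreachableError,
    TimeCourse,
    ValidationError,
)

DEFAULT_PERCENTILES = (20.0, 30.0, 40.0, 50.0)


def gompertz_curve(g_max: float, b: float, c: float, t) -> np.ndarray | float:
    """Evaluate the Gompertz cumulative-germination curve at time(s) ``t`` (hours)."""
    if not (0 < g_max <= 100):
        raise ValidationError(f"g_max must be in (0, 100], got {g_max}")
    if b <= 0 or c <= 0:
        raise ValidationError("b and c must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("t must be >= 0")
    out = g_max * np.exp(-(b / c) * np.exp(-c * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def time_to_percentile(fit: GompertzFit, g: float) -> float:
    """Closed-form time (hours) at which the fitted curve reaches ``g`` percent of sown seeds.

    Requires 0 < g < Gmax strictly; raises
    :class:`PercentileUnreachableError` otherwise, so callers can skip
    percentiles a low-germinability lot never reaches.
    """
    if g <= 0:
        raise ValidationError(f"percentile must be > 0, got {g}")
    if g >= fit.g_max:
        raise PercentileUnreachableError(
            f"percentile {g}% unreachable: fitted final germination {fit.g_max:.3f}%"
        )
    inner = -(fit.c / fit.b) * np.log(g / fit.g_max)
    return float(-np.log(inner) / fit.c)


def aggregate_replicates(courses: list[TimeCourse]) -> tuple[np.ndarray, np.ndarray]:
    """Mean cumulative-percentage curve of replicates on their union time grid.

    Percentages (100*count/n_seeds) are step-interpolated per replicate
    (last observation carried forward, zero before the first observation —
    seeds are sown ungerminated) and then averaged. All replicates must
    share one condition.
    """
    if not courses:
        raise ValidationError("need at least one replicate")
    cond = courses[0].condition
    if any(tc.condition != cond for tc in courses):
        raise ValidationError("aggregate_replicates: mixed conditions")
    grid = np.unique(np.concatenate([tc.times for tc in courses]))
    acc = np.zeros_like(grid)
    for tc in courses:
        idx = np.searchsorted(tc.times, grid, side="right") - 1
        vals = np.where(idx >= 0, tc.percent[np.clip(idx, 0, None)], 0.0)
        acc += vals
    return grid, acc / len(courses)


def _gompertz_residuals(params, t, y):
    g_max, b, c = params
    return g_max * np.exp(-(b / c) * np.exp(-c * t)) - y


def _start_sequence(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Deterministic multi-start sequence for the bounded least-squares fit.

    The base start puts Gmax at the observed maximum and the time scale at
    2/(t_last - t_first); b is tied to c through the observed half-maximum
    time via the median relation (b/c)*exp(-c*t_half) = ln 2, which centres
    the starting curve on the data.
    """
    g0 = max(float(np.max(y)), 1e-2)
    span = max(float(t[-1] - t[0]), 1e-6)
    c_base = 2.0 / span
    above = t[y >= 0.5 * np.max(y)]
    t_half = float(above[0]) if above.size else 0.5 * span
    starts = []
    for c_scale in (1.0, 0.3, 3.0, 0.1, 10.0):
        c0 = c_base * c_scale
        b0 = c0 * np.log(2.0) * np.exp(min(c0 * t_half, 40.0))
        starts.append((min(g0, 100.0), float(b0), float(c0)))
    return starts


def fit_gompertz(times, percent, n_starts: int = 5) -> GompertzFit:
    """Bounded nonlinear least-squares fit of the Gompertz curve.

    ``percent`` is the (replicate-mean) cumulative germination percentage of
    sown seeds. Uses a deterministic multi-start sequence and keeps the
    lowest-RSS solution. A lot with no germinated seeds raises
    :class:`NoGerminationError`; an under-determined curve (fewer than two
    distinct positive levels, e.g. a single jump observed only at its
    plateau) is returned with ``converged=False`` rather than dropped.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(percent, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValidationError("need >= 3 observations to fit the Gompertz curve")
    if np.max(y) <= 0:
        raise NoGerminationError("all observations are zero: no germination to fit")
    lower = np.array([1e-6, 1e-9, 1e-9])
    upper = np.array([100.0, np.inf, np.inf])
    best = None
    for start in _start_sequence(t, y)[: max(n_starts, 1)]:
        x0 = np.clip(np.asarray(start), lower, [100.0, 1e30, 1e6])
        try:
            sol = least_squares(
                _gompertz_residuals, x0, bounds=(lower, upper), args=(t, y),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - optimiser pathologies
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-10:
            best = (rss, sol)
    if best is None:
        raise ValidationError("Gompertz fit failed from every start")
    rss, sol = best
    identifiable = np.unique(y[y > 0]).size >= 2
    return GompertzFit(
        g_max=float(sol.x[0]),
        b=float(sol.x[1]),
        c=float(sol.x[2]),
        rss=rss,
        n_obs=int(t.size),
        converged=bool(sol.success) and identifiable,
    )


def percentile_rates(
    fit: GompertzFit,
    percentiles=DEFAULT_PERCENTILES,
    condition: Condition | None = None,
) -> tuple[list[PercentileRate], list[float]]:
    """Germination rates 1/t(G) for each reachable percentile.

    Returns ``(rates, skipped)`` where ``skipped`` lists percentiles at or
    above the fitted final germination percentage (omitted, never
    zero-filled).
    """
    cond = condition if condition is not None else Condition(20.0, 0.0)
    if list(percentiles) != sorted(percentiles):
        raise ValidationError("percentiles must be sorted ascending")
    rates: list[PercentileRate] = []
    skipped: list[float] = []
    for g in percentiles:
        try:
            t_g = time_to_percentile(fit, g)
        except PercentileUnreachableError:
            skipped.append(g)
            continue
        if t_g <= 0:  # percentile already exceeded at sowing: model artifact
            skipped.append(g)
            continue
        rates.append(PercentileRate(percentile_g=g, condition=cond, time_to_g=t_g, rate=1.0 / t_g))
    return rates, skipped


class GompertzModel:
    """Model object for one cumulative germination curve.

    Parameters
    ----------
    time_h, percent : array-like
        Observation times (hours) and cumulative germination as percent of
        sown seeds — typically the replicate-mean curve from
        :func:`aggregate_replicates`.
    """

    def __init__(self, time_h, percent):
        self.time_h = np.asarray(time_h, dtype=float)
        self.percent = np.asarray(percent, dtype=float)

    @classmethod
    def from_time_courses(cls, courses: list[TimeCourse]) -> "GompertzModel":
        grid, mean_pct = aggregate_replicates(courses)
        return cls(grid, mean_pct)

    def fit(self, n_starts: int = 5) -> "GompertzResults":
        return GompertzResults(self, fit_gompertz(self.time_h, self.percent, n_starts=n_starts))


class GompertzResults:
    """Fitted Gompertz curve with prediction, inversion and rate helpers."""

    def __init__(self, model: GompertzModel, params: GompertzFit):
        self.model = model
        self.params = params

    @property
    def g_max(self) -> float:
        return self.params.g_max

    @property
    def converged(self) -> bool:
        return self.params.converged

    def predict(self, t):
        return gompertz_curve(self.params.g_max, self.params.b, self.params.c, t)

    def time_to_percentile(self, g: float) -> float:
        return time_to_percentile(self.params, g)

    def percentile_rates(self, percentiles=DEFAULT_PERCENTILES, condition=None):
        """Rates for percentiles the *observed* curve actually reached.

        On top of the fitted-Gmax rule, a percentile the data never attained
        within the observation window is skipped rather than extrapolated
        from the tail of a truncated experiment.
        """
        observed_max = float(np.max(self.model.percent))
        reached = [g for g in percentiles if g <= observed_max]
        rates, skipped = percentile_rates(self.params, tuple(reached), condition)
        skipped = sorted(set(skipped) | (set(percentiles) - set(reached)))
        return rates, skipped

    def summary(self) -> str:
        p = self.params
        lines = [
            "Gompertz germination time course",
            f"  n_obs      {p.n_obs:>10d}",
            f"  Gmax (%)   {p.g_max:>10.3f}",
            f"  b          {p.b:>10.5g}",
            f"  c (1/h)    {p.c:>10.5g}",
            f"  RSS        {p.rss:>10.5g}",
            f"  converged  {str(p.converged):>10s}",
        ]
        return "\n".join(lines)
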