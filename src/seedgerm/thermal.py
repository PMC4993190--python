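"""Thermal response of germination rate: beta-function fit and base temperature.

Across sub- to supra-optimal temperatures the germination rate of a
percentile follows the beta-shaped response

    1/t(G) = exp(mu) * (T - T0)^alpha * (Tmax - T)^beta      for T0 < T < Tmax

and zero outside (T0, Tmax). T0 and Tmax are the minimum and maximum
temperatures at which germination stops; the optimum is the analytic argmax

    Topt = (alpha*Tmax + beta*T0) / (alpha + beta).

One fit is made per percentile (20, 30, 40, 50 % of sown seeds); cardinal
temperatures are the mean across the percentile fits, with the SD across
percentiles as the dispersion. The base temperature Tb used for
thermal-time accumulation is instead the x-intercept of an ordinary
least-squares line through the *linear* sub-optimal phase of rate against
temperature, again averaged over percentiles. Tb is deliberately not
clamped at 0 degC (field estimates below zero exist), whereas the
beta-function T0 is bounded at 0 by default since many species pin it there.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .types import (
    BaseLinearFit,
    CardinalTemperatures,
    EstimationError,
    InsufficientDataError,
    PercentileLine,
    ValidationError,
    YinFit,
    sample_sd,
)


def yin_rate(mu: float, alpha: float, beta: float, t0: float, tmax: float, T):
    """Beta-function germination rate (1/h) at temperature(s) ``T``; 0 outside (t0, tmax)."""
    if t0 >= tmax:
        raise ValidationError(f"t0 ({t0}) must be < tmax ({tmax})")
    T_arr = np.asarray(T, dtype=float)
    inside = (T_arr > t0) & (T_arr < tmax)
    out = np.zeros_like(T_arr, dtype=float)
    out[inside] = np.exp(mu) * (T_arr[inside] - t0) ** alpha * (tmax - T_arr[inside]) ** beta
    return float(out) if np.isscalar(T) or T_arr.ndim == 0 else out


def optimal_temperature(fit: YinFit) -> float:
    """Rate-maximising temperature of the fitted beta response.

    Setting the derivative of (T-T0)^alpha*(Tmax-T)^beta to zero gives
    Topt = (alpha*Tmax + beta*T0)/(alpha + beta), which always lies strictly
    inside (T0, Tmax).
    """
    return (fit.alpha * fit.tmax + fit.beta * fit.t0) / (fit.alpha + fit.beta)


def _yin_residuals(params, T, r):
    mu, alpha, beta, t0, tmax = params
    span0 = np.maximum(T - t0, 1e-12)
    span1 = np.maximum(tmax - T, 1e-12)
    return np.exp(mu) * span0**alpha * span1**beta - r


def fit_yin(
    temperatures,
    rates,
    percentile_g: float = 50.0,
    t0_lower: float = 0.0,
    n_starts: int = 6,
) -> YinFit:
    """Bounded least-squares fit of the beta-function thermal response.

    Only temperatures with an observed (positive) rate enter the residuals;
    the tested grid constrains the cardinal bounds: t0 in
    [``t0_lower``, min T with rate], tmax in [max T with rate, 50].
    ``t0_lower`` defaults to 0 degC (set to -5 to relax the non-negativity
    constraint). Requires >= 5 points for the 5 free parameters.
    """
    T = np.asarray(temperatures, dtype=float)
    r = np.asarray(rates, dtype=float)
    if T.size != r.size:
        raise ValidationError("temperatures and rates must have equal length")
    keep = r > 0
    T, r = T[keep], r[keep]
    if T.size < 5:
        raise InsufficientDataError(
            f"beta-function fit needs >= 5 temperatures with rates, got {T.size}"
        )
    order = np.argsort(T)
    T, r = T[order], r[order]
    t0_hi = float(T.min())
    tmax_lo = float(T.max())
    lower = np.array([-40.0, 0.05, 0.05, t0_lower, tmax_lo + 1e-6])
    upper = np.array([10.0, 12.0, 12.0, t0_hi - 1e-6, 50.0])
    if lower[3] >= upper[3]:  # grid minimum at/below the t0 floor
        upper[3] = lower[3] + 1e-6

    r_max = float(r.max())
    starts = []
    for t0_s in (max(t0_lower, 0.0), 0.5 * t0_hi):
        for tmax_s in (tmax_lo + 1.5, min(tmax_lo + 5.0, 49.0)):
            for (a_s, b_s) in ((1.5, 0.8), (2.5, 0.5)):
                t0c = float(np.clip(t0_s, lower[3], upper[3]))
                tmaxc = float(np.clip(tmax_s, lower[4], upper[4]))
                topt = (a_s * tmaxc + b_s * t0c) / (a_s + b_s)
                peak = (topt - t0c) ** a_s * (tmaxc - topt) ** b_s
                mu_s = float(np.clip(np.log(r_max / peak), lower[0], upper[0]))
                starts.append((mu_s, a_s, b_s, t0c, tmaxc))
    best = None
    for x0 in starts[: max(n_starts, 1) * 2]:
        try:
            sol = least_squares(
                _yin_residuals, np.asarray(x0), bounds=(lower, upper), args=(T, r),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:  # pragma: no cover
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-16:
            best = (rss, sol)
    if best is None:
        raise EstimationError("beta-function fit failed from every start")
    rss, sol = best
    tss = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    mu, alpha, beta, t0, tmax = (float(v) for v in sol.x)
    at_bounds = bool(
        np.any(np.isclose(sol.x[1:3], lower[1:3])) or np.any(np.isclose(sol.x[1:3], upper[1:3]))
    )
    degenerate = tss <= 1e-20  # flat rates carry no thermal signal
    return YinFit(
        percentile_g=percentile_g,
        mu=mu, alpha=alpha, beta=beta, t0=t0, tmax=tmax,
        rss=rss, r_squared=r2,
        converged=bool(sol.success) and not at_bounds and not degenerate,
    )


def cardinal_temperatures(fits: Sequence[YinFit]) -> CardinalTemperatures:
    """Aggregate per-percentile beta fits into mean +/- SD cardinal temperatures."""
    if not fits:
        raise InsufficientDataError("need at least one percentile fit")
    t0s = [f.t0 for f in fits]
    tmaxs = [f.tmax for f in fits]
    topts = [optimal_temperature(f) for f in fits]
    return CardinalTemperatures(
        t0_mean=float(np.mean(t0s)), t0_sd=sample_sd(t0s),
        topt_mean=float(np.mean(topts)), topt_sd=sample_sd(topts),
        tmax_mean=float(np.mean(tmaxs)), tmax_sd=sample_sd(tmaxs),
        percentiles_used=tuple(f.percentile_g for f in fits),
    )


def select_linear_phase(temperatures, rates, topt_hint: float) -> tuple[float, ...]:
    """Choose the sub-optimal temperature window where rate rises linearly.

    Among contiguous windows of >= 3 tested temperatures with positive rate
    strictly below ``topt_hint``, returns the window maximising the OLS R^2
    of rate on temperature; ties broken by longer window, then by lower
    starting temperature.
    """
    T = np.asarray(temperatures, dtype=float)
    r = np.asarray(rates, dtype=float)
    keep = (r > 0) & (T < topt_hint)
    T, r = T[keep], r[keep]
    order = np.argsort(T)
    T, r = T[order], r[order]
    if T.size < 3:
        raise InsufficientDataError(
            f"need >= 3 sub-optimal temperatures with rates below {topt_hint} degC, got {T.size}"
        )
    best = None
    for i in range(T.size - 2):
        for j in range(i + 3, T.size + 1):
            res = linregress(T[i:j], r[i:j])
            r2 = float(res.rvalue**2)
            key = (round(r2, 12), j - i, -T[i])  # max R^2, then longer, then lower start
            if best is None or key > best[0]:
                best = (key, tuple(T[i:j]))
    return best[1]


def fit_base_temperature(
    rates_by_percentile: Mapping[float, Sequence[tuple[float, float]]],
    window: Sequence[float],
) -> BaseLinearFit:
    """OLS x-intercept of rate vs temperature over the linear window, per percentile.

    ``rates_by_percentile`` maps percentile -> iterable of (temperature, rate)
    pairs. For each percentile with >= 3 points inside ``window`` an OLS line
    is fitted; percentiles with non-positive slope are excluded with a note.
    Tb is the mean x-intercept (-intercept/slope) across the remaining
    percentiles, with the SD across percentiles; negative Tb is permitted.
    """
    window_set = set(float(w) for w in window)
    lines: list[PercentileLine] = []
    excluded: list[float] = []
    points_used: dict[float, tuple[tuple[float, float], ...]] = {}
    for g in sorted(rates_by_percentile):
        pts = [(float(T), float(r)) for T, r in rates_by_percentile[g] if float(T) in window_set]
        if len(pts) < 3:
            excluded.append(g)
            continue
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        res = linregress(x, y)
        if res.slope <= 0:
            excluded.append(g)
            continue
        points_used[g] = tuple(pts)
        lines.append(
            PercentileLine(
                percentile_g=g,
                slope=float(res.slope),
                intercept=float(res.intercept),
                x_intercept=float(-res.intercept / res.slope),
                r_squared=float(res.rvalue**2),
                n_points=len(pts),
            )
        )
    if len(lines) < 2:
        raise EstimationError(
            "base-temperature estimation needs >= 2 percentiles with a positive linear response"
        )
    xints = [ln.x_intercept for ln in lines]
    return BaseLinearFit(
        kind="base_temperature",
        x_intercept_mean=float(np.mean(xints)),
        x_intercept_sd=sample_sd(xints),
        lines=tuple(lines),
        points_used=points_used,
        excluded_percentiles=tuple(excluded),
    )


class ThermalResponseModel:
    """Model object for one percentile's germination rate across temperatures."""

    def __init__(self, temperature_c, rate, percentile_g: float = 50.0):
        self.temperature_c = np.asarray(temperature_c, dtype=float)
        self.rate = np.asarray(rate, dtype=float)
        self.percentile_g = percentile_g

    def fit(self, t0_lower: float = 0.0) -> "ThermalResponseResults":
        params = fit_yin(
            self.temperature_c, self.rate, percentile_g=self.percentile_g, t0_lower=t0_lower
        )
        return ThermalResponseResults(self, params)


class ThermalResponseResults:
    def __init__(self, model: ThermalResponseModel, params: YinFit):
        self.model = model
        self.params = params

    @property
    def topt(self) -> float:
        return optimal_temperature(self.params)

    def predict(self, T):
        p = self.params
        return yin_rate(p.mu, p.alpha, p.beta, p.t0, p.tmax, T)

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                f"Beta-function thermal response (percentile G={p.percentile_g:g}%)",
                f"  T0 (degC)    {p.t0:>9.3f}",
                f"  Tmax (degC)  {p.tmax:>9.3f}",
                f"  Topt (degC)  {self.topt:>9.3f}",
                f"  alpha        {p.alpha:>9.4f}",
                f"  beta         {p.beta:>9.4f}",
                f"  mu           {p.mu:>9.4f}",
                f"  R^2          {p.r_squared:>9.4f}",
                f"  converged    {str(p.converged):>9s}",
            ]
        )
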