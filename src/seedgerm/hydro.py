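"""Water-potential response: base water potential and PEG-8000 calibration.

At a fixed 20 degC, germination rate declines approximately linearly as the
medium water potential Psi (MPa) becomes more negative. The base water
potential Psi_b — the most negative potential still permitting germination —
is the x-intercept of an OLS line of rate on Psi, estimated per percentile
(20th and 30th by default; higher percentiles are often unreachable under
osmotic stress) and averaged.

Water potentials are imposed with PEG-8000 solutions. Rather than the full
temperature-dependent PEG calibration, the printed concentration/potential
anchor pairs (valid at 20 degC) are interpolated piecewise-linearly:
0 MPa = 0 g/L, -0.1 = 73.7, -0.5 = 195, -0.75 = 250, -1.5 = 376.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.stats import linregress

from .types import (
    BaseLinearFit,
    EstimationError,
    InsufficientDataError,
    PercentileLine,
    ValidationError,
    sample_sd,
)

#: (psi MPa, g PEG-8000 per litre) anchors, psi ascending.
PEG_ANCHORS: tuple[tuple[float, float], ...] = (
    (-1.5, 376.0),
    (-0.75, 250.0),
    (-0.5, 195.0),
    (-0.1, 73.7),
    (0.0, 0.0),
)

_PSI = np.array([a[0] for a in PEG_ANCHORS])
_CONC = np.array([a[1] for a in PEG_ANCHORS])


def peg_concentration(psi: float) -> float:
    """g PEG-8000 per litre producing water potential ``psi`` MPa at 20 degC.

    Monotone piecewise-linear interpolation through the calibration anchors;
    no extrapolation outside [-1.5, 0] MPa.
    """
    if not (-1.5 <= psi <= 0):
        raise ValidationError(f"psi out of calibrated range [-1.5, 0] MPa: {psi}")
    return float(np.interp(psi, _PSI, _CONC))


def psi_from_peg(conc: float) -> float:
    """Inverse calibration: water potential (MPa) of a ``conc`` g/L PEG-8000 solution."""
    if not (0 <= conc <= 376):
        raise ValidationError(f"concentration out of calibrated range [0, 376] g/L: {conc}")
    # concentration is strictly decreasing in psi, so interpolate on the reversed axis
    return float(np.interp(conc, _CONC[::-1], _PSI[::-1]))


def fit_base_water_potential(
    rates_by_percentile: Mapping[float, Sequence[tuple[float, float]]],
    min_points: int = 2,
) -> BaseLinearFit:
    """OLS x-intercept of rate vs water potential, per percentile, at 20 degC.

    ``rates_by_percentile`` maps percentile -> iterable of (psi, rate) pairs;
    the pure-water (0 MPa) rate is an ordinary regression point. A species
    with a shallow Psi_b may germinate at only two potentials, so
    ``min_points`` defaults to 2 (a two-point line is exact). Rate must
    increase toward Psi = 0, i.e. the slope must be positive; percentiles
    violating this are excluded, and an :class:`EstimationError` is raised
    if none survive.
    """
    lines: list[PercentileLine] = []
    excluded: list[float] = []
    points_used: dict[float, tuple[tuple[float, float], ...]] = {}
    for g in sorted(rates_by_percentile):
        pts = [(float(p), float(r)) for p, r in rates_by_percentile[g]]
        if len(pts) < max(min_points, 2):
            excluded.append(g)
            continue
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.unique(x).size < 2:
            excluded.append(g)
            continue
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
    if not lines:
        if excluded:
            raise EstimationError(
                "base-water-potential estimation failed: no percentile shows a rate "
                "increasing toward 0 MPa with enough water potentials"
            )
        raise InsufficientDataError("no percentile rate data supplied")
    xints = [ln.x_intercept for ln in lines]
    return BaseLinearFit(
        kind="base_water_potential",
        x_intercept_mean=float(np.mean(xints)),
        x_intercept_sd=sample_sd(xints),
        lines=tuple(lines),
        points_used=points_used,
        excluded_percentiles=tuple(excluded),
    )
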