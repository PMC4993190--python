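"""Domain types for germination-response estimation.

The pipeline moves through a fixed sequence of value objects: a
:class:`TimeCourse` holds one replicate's cumulative germination counts
under one :class:`Condition`; a :class:`GompertzFit` summarises the
sigmoidal time course; :class:`PercentileRate` carries the germination
rate 1/t(G) for one seed-population percentile; :class:`YinFit` holds the
beta-function thermal response of that rate; :class:`CardinalTemperatures`
and :class:`BaseLinearFit` aggregate per-percentile estimates into the
per-species quantities (T0, Topt, Tmax, Tb, Psi_b) that finally populate a
:class:`SpeciesProfile` and feed the Ward :class:`FunctionalGrouping`.

All temperatures are degrees Celsius, times hours, water potentials MPa
(non-positive; 0 = pure water), percentages are percent of *sown* seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SCHEMA_VERSION = "1.0"


class GerminationError(Exception):
    """Base class for all seedgerm errors."""


class SchemaError(GerminationError):
    """An input table does not match the expected column schema."""


class ValidationError(GerminationError):
    """A domain invariant is violated (e.g. decreasing cumulative counts)."""


class NoGerminationError(GerminationError):
    """A time course contains no germinated seeds, so nothing can be fitted."""


class InsufficientDataError(GerminationError):
    """Too few observations/conditions to estimate the requested quantity."""


class EstimationError(GerminationError):
    """An estimator could not produce a usable result (e.g. non-positive slope)."""


class PercentileUnreachableError(GerminationError):
    """The requested percentile exceeds the fitted final germination percentage."""


@dataclass(frozen=True)
class Condition:
    """One germination environment: temperature (degC) and water potential (MPa)."""

    temperature: float
    water_potential: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise ValidationError("temperature must be finite")
        if not math.isfinite(self.water_potential) or self.water_potential > 0:
            raise ValidationError(
                f"water_potential must be finite and <= 0 MPa, got {self.water_potential}"
            )


@dataclass
class TimeCourse:
    """Cumulative germination counts of one replicate under one condition.

    ``times`` are hours since sowing (strictly increasing, >= 0) and
    ``cumulative_counts`` the number of germinated seeds at each time
    (non-decreasing, bounded by ``n_seeds``).
    """

    species_id: str
    family: str
    replicate_id: str
    condition: Condition
    times: np.ndarray
    cumulative_counts: np.ndarray
    n_seeds: int = 25
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_counts = np.asarray(self.cumulative_counts, dtype=int)
        self.validate()

    def validate(self) -> None:
        label = f"{self.species_id}/{self.replicate_id}@{self.condition.temperature}C,{self.condition.water_potential}MPa"
        if self.times.ndim != 1 or self.times.size != self.cumulative_counts.size:
            raise ValidationError(f"{label}: times and counts must be 1-D and equal length")
        if self.times.size and self.times[0] < 0:
            raise ValidationError(f"{label}: negative observation time {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            i = int(np.argmax(np.diff(self.times) <= 0))
            raise ValidationError(f"{label}: times not strictly increasing at t={self.times[i + 1]}")
        if self.n_seeds < 1:
            raise ValidationError(f"{label}: n_seeds must be >= 1")
        if np.any(self.cumulative_counts < 0) or np.any(self.cumulative_counts > self.n_seeds):
            raise ValidationError(f"{label}: counts outside [0, n_seeds={self.n_seeds}]")
        diffs = np.diff(self.cumulative_counts)
        if np.any(diffs < 0):
            i = int(np.argmax(diffs < 0))
            raise ValidationError(
                f"{label}: cumulative counts decrease at t={self.times[i + 1]} "
                f"({self.cumulative_counts[i]} -> {self.cumulative_counts[i + 1]})"
            )

    @property
    def percent(self) -> np.ndarray:
        """Cumulative germination as percent of sown seeds."""
        return 100.0 * self.cumulative_counts / self.n_seeds


@dataclass
class GompertzFit:
    """Least-squares fit of the Gompertz curve G(t) = Gmax*exp[-(b/c)*exp(-c*t)]."""

    g_max: float
    b: float
    c: float
    rss: float
    n_obs: int
    converged: bool

    def __post_init__(self) -> None:
        if not (0 < self.g_max <= 100):
            raise ValidationError(f"g_max must be in (0, 100], got {self.g_max}")
        if self.b <= 0 or self.c <= 0:
            raise ValidationError("Gompertz shape parameters b, c must be > 0")
        if self.rss < 0:
            raise ValidationError("rss must be >= 0")


@dataclass(frozen=True)
class PercentileRate:
    """Germination rate 1/t(G) for one percentile G of the sown seed population."""

    percentile_g: float
    condition: Condition
    time_to_g: float
    rate: float

    def __post_init__(self) -> None:
        if self.time_to_g <= 0 or self.rate <= 0:
            raise ValidationError("time_to_g and rate must be > 0")
        if not math.isclose(self.rate, 1.0 / self.time_to_g, rel_tol=1e-9):
            raise ValidationError("rate must equal 1/time_to_g")


@dataclass
class YinFit:
    """Beta-function thermal response 1/t(G) = exp(mu)*(T-t0)^alpha*(tmax-T)^beta."""

    percentile_g: float
    mu: float
    alpha: float
    beta: float
    t0: float
    tmax: float
    rss: float
    r_squared: float
    converged: bool

    def __post_init__(self) -> None:
        if self.t0 >= self.tmax:
            raise ValidationError(f"t0 ({self.t0}) must be < tmax ({self.tmax})")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("alpha and beta must be > 0")


@dataclass
class CardinalTemperatures:
    """Per-species cardinal temperatures: mean and SD across percentile fits."""

    t0_mean: float
    t0_sd: float
    topt_mean: float
    topt_sd: float
    tmax_mean: float
    tmax_sd: float
    percentiles_used: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.t0_mean <= self.topt_mean <= self.tmax_mean):
            raise ValidationError(
                f"cardinal ordering violated: t0={self.t0_mean}, topt={self.topt_mean}, tmax={self.tmax_mean}"
            )
        if min(self.t0_sd, self.topt_sd, self.tmax_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")


@dataclass(frozen=True)
class PercentileLine:
    """One percentile's OLS line of rate against temperature or water potential."""

    percentile_g: float
    slope: float
    intercept: float
    x_intercept: float
    r_squared: float
    n_points: int


@dataclass
class BaseLinearFit:
    """Linear-phase x-intercept estimate: base temperature (Tb) or base water potential (Psi_b).

    Per-percentile OLS lines (rate on temperature, or rate on water potential)
    are extrapolated to zero rate; the x-intercepts are averaged across
    percentiles. ``points_used`` records the (x, rate) pairs per percentile.
    """

    kind: str  # "base_temperature" | "base_water_potential"
    x_intercept_mean: float
    x_intercept_sd: float
    lines: tuple[PercentileLine, ...]
    points_used: Mapping[float, tuple[tuple[float, float], ...]]
    excluded_percentiles: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("base_temperature", "base_water_potential"):
            raise ValidationError(f"unknown kind {self.kind!r}")

    @property
    def percentiles_used(self) -> tuple[float, ...]:
        return tuple(line.percentile_g for line in self.lines)


@dataclass
class SpeciesProfile:
    """Per-species germination trait vector (Table-1-style row).

    Any trait a stage could not estimate is NaN; ``notes`` records why.
    """

    species_id: str
    family: str = ""
    seed_mass_mg: float = float("nan")
    t0: float = float("nan")
    topt: float = float("nan")
    tmax: float = float("nan")
    tb: float = float("nan")
    psi_b: float = float("nan")
    g_max_best: float = float("nan")
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if math.isfinite(self.t0) and math.isfinite(self.topt) and math.isfinite(self.tmax):
            if not (self.t0 <= self.topt <= self.tmax):
                raise ValidationError(
                    f"{self.species_id}: cardinal ordering violated "
                    f"(t0={self.t0}, topt={self.topt}, tmax={self.tmax})"
                )
        if math.isfinite(self.psi_b) and self.psi_b > 0:
            raise ValidationError(f"{self.species_id}: psi_b must be <= 0, got {self.psi_b}")


@dataclass(frozen=True)
class MergeRecord:
    """One agglomerative merge: clusters ``left`` and ``right`` joined at ``height``.

    Cluster ids follow the scipy convention: 0..n-1 are singletons, the i-th
    merge creates cluster n+i. ``height`` is the increase in total
    within-cluster variance (squared-Euclidean Ward cost) of the merge.
    """

    left: int
    right: int
    height: float
    size: int


@dataclass
class FunctionalGrouping:
    """Result of Ward hierarchical classification cut at k groups."""

    k: int
    labels: Mapping[str, int]
    linkage: tuple[MergeRecord, ...]
    feature_names: tuple[str, ...]
    standardized: bool

    def __post_init__(self) -> None:
        groups = set(self.labels.values())
        if len(groups) != self.k:
            raise ValidationError(f"expected exactly {self.k} groups, found {len(groups)}")

    def members(self, group: int) -> list[str]:
        return sorted(s for s, g in self.labels.items() if g == group)


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (ddof=1); 0.0 for a single value."""
    arr = np.asarray(values, dtype=float)
    if arr.size <= 1:
        return 0.0
    return float(np.std(arr, ddof=1))
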