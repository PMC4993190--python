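"""Synthetic germination experiments with known ground truth.

The generator emulates the laboratory design the estimation pipeline
assumes: 4 replicates of 25 seeds per condition, observed on a 2-hour
camera grid (8-hour manual counts for incubator conditions), across a
temperature grid spanning 4.5-43 degC and a water-potential grid at
20 degC. Each virtual species carries a beta-function thermal response
(the ground-truth cardinal temperatures), a base water potential entering
as a linear rate reduction factor max(0, 1 - psi/psi_b), a final-germination
profile over temperature (one of the two shapes seen in real lots: a
plateau collapsing only near Tmax, or additionally depressed near T0), and
a Gompertz-shaped distribution of individual germination times.

Seed-level sampling: a seed germinates with probability g_max(T)/100 and,
if it does, draws its germination time from the normalised Gompertz
distribution whose median is 1/rate(T, psi) and whose relative dispersion
is set by ``spread`` (larger = steeper, more synchronous lots). Counts are
reported cumulatively on the observation grid, so the expected cumulative
curve is exactly a Gompertz function of time — the model the pipeline fits.

Reproducibility: one root seed; each time course draws from an independent
stream derived by stable hashing of (species, condition, replicate), so any
subset of the experiment reproduces bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .thermal import yin_rate
from .types import Condition, TimeCourse, ValidationError

LN2 = float(np.log(2.0))

DEFAULT_TEMPERATURE_GRID = (4.5, 11.5, 15.0, 20.0, 26.7, 31.0, 36.0, 39.5, 43.0)
DEFAULT_PSI_GRID = (0.0, -0.1, -0.5, -0.75)
EXTRA_PSI = (-0.9, -1.5)
#: temperatures handled on the imaging table; everything else runs in incubators
CAMERA_RANGE = (11.5, 36.0)


@dataclass(frozen=True)
class TrueSpecies:
    """Ground-truth germination parameters of one virtual species."""

    species_id: str
    family: str = "Synthaceae"
    mu: float = -11.7  # peak rate ~0.04/h for the default shape below
    alpha: float = 2.0
    beta: float = 0.8
    t0: float = 1.0
    tmax: float = 38.0
    psi_b: float = -1.0
    g_max_plateau: float = 90.0
    g_max_profile: str = "plateau_drop_high"  # or "drop_both_ends"
    spread: float = 5.0

    def __post_init__(self) -> None:
        if self.t0 >= self.tmax:
            raise ValidationError("t0 must be < tmax")
        if self.psi_b >= 0:
            raise ValidationError("psi_b must be < 0")
        if not (0 < self.g_max_plateau <= 100):
            raise ValidationError("g_max_plateau must be in (0, 100]")
        if self.spread <= 0:
            raise ValidationError("spread must be > 0")
        if self.g_max_profile not in ("plateau_drop_high", "drop_both_ends"):
            raise ValidationError(f"unknown g_max_profile {self.g_max_profile!r}")

    @property
    def topt(self) -> float:
        return (self.alpha * self.tmax + self.beta * self.t0) / (self.alpha + self.beta)


def g_max_at(sp: TrueSpecies, T: float) -> float:
    """Final germination percentage at temperature ``T`` under the species profile.

    ``plateau_drop_high`` holds the plateau then falls linearly to 0 between
    0.9*tmax and tmax; ``drop_both_ends`` additionally ramps from half the
    plateau at t0 up to the full plateau by t0 + 5 degC.
    """
    if T <= sp.t0 or T >= sp.tmax:
        return 0.0
    g = sp.g_max_plateau
    knee = 0.9 * sp.tmax
    if T > knee:
        g *= (sp.tmax - T) / (sp.tmax - knee)
    if sp.g_max_profile == "drop_both_ends" and T < sp.t0 + 5.0:
        g *= 0.5 + 0.5 * (T - sp.t0) / 5.0
    return g


def _norm_quantile(q, spread: float):
    """Quantile of the normalised (median 1) Gompertz germination-time distribution."""
    q = np.asarray(q, dtype=float)
    out = 1.0 - np.log(np.log(1.0 / q) / LN2) / spread
    return np.maximum(out, 0.0)


def normalized_gompertz_cdf(tau, spread: float):
    """CDF of the normalised germination-time distribution at relative time ``tau``."""
    tau = np.asarray(tau, dtype=float)
    return np.exp(-LN2 * np.exp(spread * (1.0 - tau)))


def percentile_scaling(g: float, spread: float) -> float:
    """Rate multiplier for percentile ``g`` (percent); 1 at the median, > 1 below it."""
    if not (0 < g < 100):
        raise ValidationError("percentile must be in (0, 100)")
    return 1.0 / float(_norm_quantile(g / 100.0, spread))


def true_rate(sp: TrueSpecies, T: float, psi: float = 0.0, g: float = 50.0) -> float:
    """Ground-truth germination rate: thermal beta response x linear hydro
    reduction x percentile scaling."""
    thermal = yin_rate(sp.mu, sp.alpha, sp.beta, sp.t0, sp.tmax, T)
    hydro = max(0.0, 1.0 - psi / sp.psi_b)
    return thermal * hydro * percentile_scaling(g, sp.spread)


def _stream(root_seed: int, sp: TrueSpecies, cond: Condition, replicate_id: str) -> np.random.Generator:
    key = f"{sp.species_id}|{cond.temperature:.6g}|{cond.water_potential:.6g}|{replicate_id}"
    return np.random.default_rng(
        np.random.SeedSequence((int(root_seed) % (2**31), zlib.crc32(key.encode())))
    )


def simulate_time_course(
    sp: TrueSpecies,
    condition: Condition,
    n_seeds: int = 25,
    interval: float = 2.0,
    horizon: float = 1000.0,
    rng: np.random.Generator | None = None,
    replicate_id: str = "r1",
    noise: bool = True,
) -> TimeCourse:
    """One replicate's cumulative counts on the observation grid.

    With ``noise=False`` the binomial seed lot is replaced by its
    expectation (counts = floor of expected cumulative count), which with a
    large ``n_seeds`` gives an effectively continuous noiseless curve.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    grid = np.arange(interval, horizon + 1e-9, interval)
    T, psi = condition.temperature, condition.water_potential
    r50 = true_rate(sp, T, psi, 50.0)
    warnings: tuple[str, ...] = ()
    if r50 <= 0:
        counts = np.zeros(grid.size, dtype=int)
    else:
        t50 = 1.0 / r50
        if t50 > horizon:
            warnings = ("truncated: median germination time exceeds the observation horizon",)
        p_germ = g_max_at(sp, T) / 100.0
        cdf = normalized_gompertz_cdf(grid / t50, sp.spread)
        if noise:
            k = rng.binomial(n_seeds, p_germ)
            times = t50 * _norm_quantile(rng.uniform(size=k), sp.spread)
            counts = np.searchsorted(np.sort(times), grid, side="right").astype(int)
        else:
            counts = np.floor(n_seeds * p_germ * cdf).astype(int)
    return TimeCourse(
        species_id=sp.species_id,
        family=sp.family,
        replicate_id=replicate_id,
        condition=condition,
        times=grid,
        cumulative_counts=counts,
        n_seeds=n_seeds,
        warnings=warnings,
    )


@dataclass
class SimulationConfig:
    """Design of a full factorial germination experiment.

    ``observation_interval`` applies to imaging-table temperatures (within
    ``CAMERA_RANGE``); ``incubator_interval`` to extreme temperatures and to
    every water-potential run. When ``adaptive_extra_psi`` is set, the
    additional potentials -0.9 and -1.5 MPa are run for species whose
    germination remains substantial at -0.75 MPa (hydro factor > 0.25), as
    an osmotic-stress protocol would.
    """

    species: Sequence[TrueSpecies]
    temperature_grid: Sequence[float] = DEFAULT_TEMPERATURE_GRID
    psi_grid: Sequence[float] = DEFAULT_PSI_GRID
    psi_test_temperature: float = 20.0
    n_seeds: int = 25
    n_replicates: int = 4
    observation_interval: float = 2.0
    incubator_interval: float = 8.0
    horizon: float = 1000.0
    rng_seed: int = 0
    adaptive_extra_psi: bool = False
    noise: bool = True

    def __post_init__(self) -> None:
        if not self.species or not len(self.temperature_grid) or not len(self.psi_grid):
            raise ValidationError("species and grids must be non-empty")
        if self.n_seeds < 1 or self.horizon <= 0:
            raise ValidationError("n_seeds must be >= 1 and horizon > 0")


def _species_conditions(cfg: SimulationConfig, sp: TrueSpecies) -> list[tuple[Condition, float, str]]:
    conds: list[tuple[Condition, float, str]] = []
    lo, hi = CAMERA_RANGE
    for T in cfg.temperature_grid:
        interval = cfg.observation_interval if lo <= T <= hi else cfg.incubator_interval
        conds.append((Condition(float(T), 0.0), interval, "r"))
    psis = list(cfg.psi_grid)
    if cfg.adaptive_extra_psi and (1.0 - (-0.75) / sp.psi_b) > 0.25:
        psis += [p for p in EXTRA_PSI if p not in psis]
    for psi in psis:
        conds.append((Condition(cfg.psi_test_temperature, float(psi)), cfg.incubator_interval, "w"))
    return conds


def simulate_experiment(cfg: SimulationConfig) -> tuple[list[TimeCourse], pd.DataFrame]:
    """Full factorial species x condition x replicate experiment.

    Returns the time courses plus a ground-truth table (one row per species,
    including the derived true Topt) for recovery scoring. Temperature runs
    use replicate ids r1..rN, water-potential runs w1..wN, mirroring the two
    physically separate experiments.
    """
    courses: list[TimeCourse] = []
    for sp in cfg.species:
        for cond, interval, prefix in _species_conditions(cfg, sp):
            for i in range(cfg.n_replicates):
                rep = f"{prefix}{i + 1}"
                courses.append(
                    simulate_time_course(
                        sp, cond,
                        n_seeds=cfg.n_seeds,
                        interval=interval,
                        horizon=cfg.horizon,
                        rng=_stream(cfg.rng_seed, sp, cond, rep),
                        replicate_id=rep,
                        noise=cfg.noise,
                    )
                )
    truth = pd.DataFrame(
        [
            {
                "species_id": sp.species_id,
                "family": sp.family,
                "mu": sp.mu, "alpha": sp.alpha, "beta": sp.beta,
                "t0": sp.t0, "tmax": sp.tmax, "topt": sp.topt,
                "psi_b": sp.psi_b,
                "g_max_plateau": sp.g_max_plateau,
                "g_max_profile": sp.g_max_profile,
                "spread": sp.spread,
            }
            for sp in cfg.species
        ]
    )
    return courses, truth


def sample_table1_like_species(
    n: int, seed: int, g_max_range: tuple[float, float] = (70.0, 100.0)
) -> list[TrueSpecies]:
    """Draw ``n`` virtual species spanning the trait ranges of the reference table.

    t0 uniform on [0, 11] degC, tmax uniform on [max(29, t0+25), 43] degC
    (every reference species keeps at least ~25 degC between its thermal
    limits), psi_b uniform on [-2.6, -0.15] MPa, beta-function shapes with a
    gradual sub-optimal rise and sharp supra-optimal fall, and peak rates of
    0.02-0.07 1/h (germination medians of roughly 14-50 h at the optimum).
    """
    rng = np.random.default_rng(seed)
    species = []
    for i in range(n):
        t0 = float(rng.uniform(0.0, 11.0))
        tmax = float(rng.uniform(max(29.0, t0 + 25.0), 43.0))
        alpha = float(rng.uniform(1.3, 3.0))
        beta = float(rng.uniform(0.4, 1.2))
        topt = (alpha * tmax + beta * t0) / (alpha + beta)
        peak_shape = (topt - t0) ** alpha * (tmax - topt) ** beta
        r_opt = float(rng.uniform(0.02, 0.07))
        species.append(
            TrueSpecies(
                species_id=f"SYN{i + 1:02d}",
                family="Synthaceae",
                mu=float(np.log(r_opt / peak_shape)),
                alpha=alpha,
                beta=beta,
                t0=t0,
                tmax=tmax,
                psi_b=float(rng.uniform(-2.6, -0.15)),
                g_max_plateau=float(rng.uniform(*g_max_range)),
                g_max_profile="plateau_drop_high" if i % 2 == 0 else "drop_both_ends",
                spread=float(rng.uniform(4.0, 7.0)),
            )
        )
    return species
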