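"""End-to-end per-species estimation: time courses -> germination trait profile.

:class:`SpeciesGerminationModel` chains the pipeline stages for one species:

1. replicate-mean cumulative curves per condition, Gompertz-fitted;
2. percentile germination rates 1/t(G) for G = 20, 30, 40, 50 % of sown
   seeds (percentiles above the fitted final germination are skipped);
3. one beta-function thermal fit per percentile across the pure-water
   temperature series, aggregated into cardinal temperatures (mean +/- SD
   across percentiles) with Topt from the analytic argmax;
4. base temperature from the OLS x-intercept over the automatically
   selected linear sub-optimal window (window shared across percentiles,
   chosen on the 50th-percentile rates when available);
5. base water potential from the OLS x-intercept of rate on water
   potential at the osmotic-test temperature (20th/30th percentiles).

Stages that fail for a species leave NaN in the profile and a note; they
are never silently fatal, so a multi-species dataset always yields a full
profile table.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gompertz import DEFAULT_PERCENTILES, GompertzModel, GompertzResults, aggregate_replicates
from .hydro import fit_base_water_potential
from .io import read_time_courses
from .thermal import (
    cardinal_temperatures,
    fit_base_temperature,
    fit_yin,
    optimal_temperature,
    select_linear_phase,
)
from .types import (
    BaseLinearFit,
    CardinalTemperatures,
    Condition,
    GerminationError,
    GompertzFit,
    SpeciesProfile,
    TimeCourse,
    ValidationError,
    YinFit,
)

DEFAULT_HYDRO_PERCENTILES = (20.0, 30.0)


def _grid_step(times: np.ndarray) -> float:
    """Characteristic observation interval of a grid (median spacing)."""
    times = np.asarray(times, dtype=float)
    return float(np.median(np.diff(times))) if times.size > 1 else float("inf")


class SpeciesGerminationModel:
    """Germination-response model for one species' experiment.

    ``curves`` maps each condition to one or more experimental runs, each a
    ``(times, percent)`` replicate-mean curve. Replicates observed on
    different time grids (e.g. a 2-hour imaging run and an 8-hour incubator
    run of the same condition) are separate runs: pooling them through
    carried-forward steps would lag the mean curve of the denser run.
    """

    def __init__(
        self,
        curves: Mapping[Condition, object],
        species_id: str,
        family: str = "",
        percentiles: Sequence[float] = DEFAULT_PERCENTILES,
        hydro_percentiles: Sequence[float] = DEFAULT_HYDRO_PERCENTILES,
        t0_lower: float = 0.0,
    ):
        self.curves: dict[Condition, list[tuple[np.ndarray, np.ndarray]]] = {}
        for cond, runs in curves.items():
            if isinstance(runs, tuple) and len(runs) == 2 and not isinstance(runs[0], tuple):
                runs = [runs]  # single (times, percent) pair
            self.curves[cond] = [
                (np.asarray(t, dtype=float), np.asarray(p, dtype=float)) for t, p in runs
            ]
        self.species_id = species_id
        self.family = family
        self.percentiles = tuple(percentiles)
        self.hydro_percentiles = tuple(hydro_percentiles)
        self.t0_lower = t0_lower

    @classmethod
    def from_time_courses(cls, courses: Sequence[TimeCourse], **kwargs) -> "SpeciesGerminationModel":
        """Build from replicate time courses of a single species.

        Replicates sharing a condition *and* an observation grid are averaged
        into one curve; same-condition runs on a different grid stay separate.
        """
        species = {tc.species_id for tc in courses}
        if len(species) != 1:
            raise ValidationError(f"expected one species, got {sorted(species)}")
        by_run: dict[tuple[Condition, float], list[TimeCourse]] = defaultdict(list)
        for tc in courses:
            by_run[(tc.condition, round(_grid_step(tc.times), 6))].append(tc)
        curves: dict[Condition, list[tuple[np.ndarray, np.ndarray]]] = defaultdict(list)
        for (cond, _), reps in sorted(by_run.items(), key=lambda kv: (kv[0][0].water_potential, kv[0][0].temperature, kv[0][1])):
            curves[cond].append(aggregate_replicates(reps))
        return cls(
            dict(curves), species_id=species.pop(), family=courses[0].family, **kwargs
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, species_id: str, **kwargs) -> "SpeciesGerminationModel":
        """Build from a tidy long-format frame (the canonical CSV schema)."""
        from .io import time_courses_to_frame  # noqa: F401  (schema doc)
        sub = df[df["species_id"] == species_id]
        if sub.empty:
            raise ValidationError(f"species {species_id!r} not present in the data")
        import io as _io

        buf = _io.StringIO()
        sub.to_csv(buf, index=False)
        buf.seek(0)
        courses = read_time_courses(buf)
        return cls.from_time_courses(courses, **kwargs)

    def fit(self) -> "SpeciesProfileResults":
        notes: list[str] = []
        gompertz: dict[tuple[Condition, float], GompertzResults] = {}
        skipped: dict[Condition, tuple[float, ...]] = {}
        for cond in sorted(self.curves, key=lambda c: (c.water_potential, c.temperature)):
            for times, pct in self.curves[cond]:
                try:
                    res = GompertzModel(times, pct).fit()
                except GerminationError:
                    continue  # no germination under this condition: informative absence
                gompertz[(cond, _grid_step(times))] = res
                _, skip = res.percentile_rates(self.percentiles, cond)
                if skip:
                    skipped[cond] = tuple(sorted(set(skipped.get(cond, ())) | set(skip)))

        # thermal series: per temperature at psi=0, the densest-grid run
        thermal_rates: dict[float, list[tuple[float, float]]] = defaultdict(list)
        best_thermal: dict[float, tuple[float, GompertzResults]] = {}
        for (cond, step), res in gompertz.items():
            if cond.water_potential == 0:
                if cond.temperature not in best_thermal or step < best_thermal[cond.temperature][0]:
                    best_thermal[cond.temperature] = (step, res)
        for T, (step, res) in best_thermal.items():
            rates, _ = res.percentile_rates(self.percentiles, Condition(T, 0.0))
            for pr in rates:
                thermal_rates[pr.percentile_g].append((T, pr.rate))

        # hydro series: per water potential at the osmotic-test temperature,
        # the run whose grid matches the osmotic batch (modal step of psi<0 runs)
        hydro_rates: dict[float, list[tuple[float, float]]] = defaultdict(list)
        hydro_temps = {c.temperature for c in self.curves if c.water_potential < 0}
        hydro_temp = hydro_temps.pop() if len(hydro_temps) == 1 else None
        if hydro_temp is not None:
            neg_steps = [s for (c, s) in gompertz if c.water_potential < 0]
            modal_step = max(set(neg_steps), key=neg_steps.count) if neg_steps else None
            best_hydro: dict[float, tuple[float, GompertzResults]] = {}
            for (cond, step), res in gompertz.items():
                if cond.temperature != hydro_temp:
                    continue
                dist = abs(step - modal_step) if modal_step is not None else 0.0
                cur = best_hydro.get(cond.water_potential)
                if cur is None or dist < cur[0]:
                    best_hydro[cond.water_potential] = (dist, res)
            for psi, (_, res) in best_hydro.items():
                rates, _ = res.percentile_rates(self.percentiles, Condition(hydro_temp, psi))
                for pr in rates:
                    if pr.percentile_g in self.hydro_percentiles:
                        hydro_rates[pr.percentile_g].append((psi, pr.rate))

        yin_fits: list[YinFit] = []
        for g in self.percentiles:
            pts = thermal_rates.get(g, [])
            if len(pts) < 5:
                notes.append(f"thermal fit skipped for percentile {g:g}%: {len(pts)} temperatures")
                continue
            T, r = zip(*pts)
            try:
                yin_fits.append(fit_yin(T, r, percentile_g=g, t0_lower=self.t0_lower))
            except GerminationError as exc:
                notes.append(f"thermal fit failed for percentile {g:g}%: {exc}")

        cardinal: CardinalTemperatures | None = None
        if yin_fits:
            cardinal = cardinal_temperatures(yin_fits)
        else:
            notes.append("no percentile could be fitted across temperatures")

        tb_fit: BaseLinearFit | None = None
        window: tuple[float, ...] = ()
        if cardinal is not None:
            g_sel = max(
                (g for g in self.percentiles if g in thermal_rates),
                default=None,
            )
            if 50.0 in thermal_rates:
                g_sel = 50.0
            try:
                T, r = zip(*thermal_rates[g_sel])
                window = select_linear_phase(T, r, topt_hint=cardinal.topt_mean)
                tb_fit = fit_base_temperature(thermal_rates, window)
            except GerminationError as exc:
                notes.append(f"base-temperature estimation failed: {exc}")

        psi_fit: BaseLinearFit | None = None
        if hydro_rates:
            try:
                psi_fit = fit_base_water_potential(hydro_rates)
            except GerminationError as exc:
                notes.append(f"base-water-potential estimation failed: {exc}")
        else:
            notes.append("no water-potential series available")

        g_max_best = max((res.g_max for res in gompertz.values()), default=float("nan"))
        profile = SpeciesProfile(
            species_id=self.species_id,
            family=self.family,
            t0=cardinal.t0_mean if cardinal else float("nan"),
            topt=cardinal.topt_mean if cardinal else float("nan"),
            tmax=cardinal.tmax_mean if cardinal else float("nan"),
            tb=tb_fit.x_intercept_mean if tb_fit else float("nan"),
            psi_b=psi_fit.x_intercept_mean if psi_fit else float("nan"),
            g_max_best=g_max_best,
            notes=tuple(notes),
        )
        return SpeciesProfileResults(
            model=self,
            profile=profile,
            gompertz_fits=gompertz,
            skipped_percentiles=skipped,
            thermal_rates=dict(thermal_rates),
            hydro_rates=dict(hydro_rates),
            yin_fits=tuple(yin_fits),
            cardinal=cardinal,
            linear_window=window,
            base_temperature=tb_fit,
            base_water_potential=psi_fit,
        )


class SpeciesProfileResults:
    """Fitted per-species germination profile with all intermediate estimates."""

    def __init__(
        self,
        model: SpeciesGerminationModel,
        profile: SpeciesProfile,
        gompertz_fits: Mapping[Condition, GompertzResults],
        skipped_percentiles: Mapping[Condition, tuple[float, ...]],
        thermal_rates: Mapping[float, list[tuple[float, float]]],
        hydro_rates: Mapping[float, list[tuple[float, float]]],
        yin_fits: tuple[YinFit, ...],
        cardinal: CardinalTemperatures | None,
        linear_window: tuple[float, ...],
        base_temperature: BaseLinearFit | None,
        base_water_potential: BaseLinearFit | None,
    ):
        self.model = model
        self.profile = profile
        self.gompertz_fits = dict(gompertz_fits)
        self.skipped_percentiles = dict(skipped_percentiles)
        self.thermal_rates = dict(thermal_rates)
        self.hydro_rates = dict(hydro_rates)
        self.yin_fits = yin_fits
        self.cardinal = cardinal
        self.linear_window = linear_window
        self.base_temperature = base_temperature
        self.base_water_potential = base_water_potential

    @property
    def mean_yin_r_squared(self) -> float:
        if not self.yin_fits:
            return float("nan")
        return float(np.mean([f.r_squared for f in self.yin_fits]))

    def row(self) -> dict:
        p, c = self.profile, self.cardinal
        tb, psi = self.base_temperature, self.base_water_potential
        return {
            "species_id": p.species_id,
            "family": p.family,
            "g_max_best": p.g_max_best,
            "t0": p.t0, "t0_sd": c.t0_sd if c else float("nan"),
            "topt": p.topt, "topt_sd": c.topt_sd if c else float("nan"),
            "tmax": p.tmax, "tmax_sd": c.tmax_sd if c else float("nan"),
            "tb": p.tb, "tb_sd": tb.x_intercept_sd if tb else float("nan"),
            "psi_b": p.psi_b, "psi_b_sd": psi.x_intercept_sd if psi else float("nan"),
            "mean_yin_r2": self.mean_yin_r_squared,
            "notes": "; ".join(p.notes),
        }

    def summary(self) -> str:
        p = self.profile
        lines = [
            f"Germination profile: {p.species_id} ({p.family or 'family unknown'})",
            f"  final germination (best)   {p.g_max_best:8.1f} %",
            f"  T0   (degC)                {p.t0:8.1f}  +/- {self.cardinal.t0_sd if self.cardinal else float('nan'):.1f}",
            f"  Topt (degC)                {p.topt:8.1f}  +/- {self.cardinal.topt_sd if self.cardinal else float('nan'):.1f}",
            f"  Tmax (degC)                {p.tmax:8.1f}  +/- {self.cardinal.tmax_sd if self.cardinal else float('nan'):.1f}",
            f"  Tb   (degC)                {p.tb:8.1f}",
            f"  Psi_b (MPa)                {p.psi_b:8.2f}",
            f"  mean thermal-fit R^2       {self.mean_yin_r_squared:8.3f}",
        ]
        if self.linear_window:
            lines.append(f"  linear window (degC)       {', '.join(f'{t:g}' for t in self.linear_window)}")
        if p.notes:
            lines.append("  notes: " + "; ".join(p.notes))
        return "\n".join(lines)


def profile_time_courses(
    courses: Sequence[TimeCourse], **kwargs
) -> tuple[pd.DataFrame, dict[str, SpeciesProfileResults]]:
    """Fit every species in a dataset; returns (profile table, per-species results).

    Species failing a stage get NaN traits and a note instead of aborting
    the run.
    """
    by_species: dict[str, list[TimeCourse]] = defaultdict(list)
    for tc in courses:
        by_species[tc.species_id].append(tc)
    rows, results = [], {}
    for sid in sorted(by_species):
        res = SpeciesGerminationModel.from_time_courses(by_species[sid], **kwargs).fit()
        results[sid] = res
        rows.append(res.row())
    return pd.DataFrame(rows), results


def profile_dataframe(df: pd.DataFrame, **kwargs):
    """Like :func:`profile_time_courses` but from the tidy long frame."""
    import io as _io

    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return profile_time_courses(read_time_courses(buf), **kwargs)
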