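"""Tidy-CSV readers/writers, JSON serialisation and packaged reference tables.

The canonical on-disk form of an experiment is a long/tidy CSV with one row
per observation time and *cumulative* germinated counts::

    species_id,family,replicate_id,temperature_C,water_potential_MPa,time_h,cum_germinated,n_seeds

UTF-8, decimal points, ``#``-prefixed header comments carrying the schema
version. A missing ``water_potential_MPa`` column defaults to 0 MPa
(pure-water experiments); a missing ``family`` defaults to "".
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    SCHEMA_VERSION,
    Condition,
    SchemaError,
    TimeCourse,
    ValidationError,
)

REQUIRED_COLUMNS = ("species_id", "replicate_id", "temperature_C", "time_h", "cum_germinated", "n_seeds")
OPTIONAL_COLUMNS = {"family": "", "water_potential_MPa": 0.0}

#: Functional group 1 is the only group whose full membership the source
#: study enumerates in the text (the two tropical, high-T0 taxa); the other
#: group memberships are shown only graphically and are not packaged.
GROUP1_SPECIES = ("Guizotia abyssinica", "Setaria italica")


def read_time_courses(path: str | Path) -> list[TimeCourse]:
    """Read a tidy germination CSV into validated :class:`TimeCourse` objects.

    Rows are grouped by (species, replicate, temperature, water potential)
    and sorted by time within each group. Raises :class:`SchemaError` when a
    required column is missing and :class:`ValidationError` when counts
    decrease or invariants are otherwise violated.
    """
    df = pd.read_csv(path, comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default
    courses: list[TimeCourse] = []
    keys = ["species_id", "replicate_id", "temperature_C", "water_potential_MPa"]
    for (species, rep, temp, psi), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        n_seeds = grp["n_seeds"].unique()
        if len(n_seeds) != 1:
            raise ValidationError(f"{species}/{rep}: inconsistent n_seeds within one replicate")
        courses.append(
            TimeCourse(
                species_id=str(species),
                family=str(grp["family"].iloc[0]),
                replicate_id=str(rep),
                condition=Condition(float(temp), float(psi)),
                times=grp["time_h"].to_numpy(float),
                cumulative_counts=grp["cum_germinated"].to_numpy(),
                n_seeds=int(n_seeds[0]),
            )
        )
    return courses


def time_courses_to_frame(courses: Iterable[TimeCourse]) -> pd.DataFrame:
    """Flatten time courses back into the tidy long schema."""
    rows = []
    for tc in courses:
        for t, n in zip(tc.times, tc.cumulative_counts):
            rows.append(
                {
                    "species_id": tc.species_id,
                    "family": tc.family,
                    "replicate_id": tc.replicate_id,
                    "temperature_C": tc.condition.temperature,
                    "water_potential_MPa": tc.condition.water_potential,
                    "time_h": t,
                    "cum_germinated": int(n),
                    "n_seeds": tc.n_seeds,
                }
            )
    return pd.DataFrame(rows)


def write_time_courses(courses: Iterable[TimeCourse], path: str | Path) -> None:
    df = time_courses_to_frame(courses)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def load_table1_fixture() -> pd.DataFrame:
    """Packaged per-species reference table: seed mass, cardinal temperatures and Tb.

    36 taxa from 6 families. Means and ``*_sd`` columns are taken across the
    four germination percentiles (20, 30, 40, 50 % of sown seeds); the source
    footnote calls the dispersion a standard error, but the values behave as
    SDs over the four percentile estimates, hence the column naming. Base
    water potential is not part of this table.
    """
    ref = resources.files("seedgerm.fixtures") / "table1_cardinal_temperatures.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(objects: Sequence, path: str | Path, format: str = "csv") -> None:
    """Serialise a homogeneous collection of result dataclasses.

    ``json`` is loss-free (full float precision, nested fields kept);
    ``csv`` flattens scalar fields and adds a ``*_1dp`` display column
    rounded to one decimal for every float field, matching the reporting
    convention of the reference tables. An empty collection yields a
    header-only file (csv) or an empty list (json).
    """
    path = Path(path)
    if objects and len({type(o) for o in objects}) != 1:
        raise ValueError("write_results requires objects of a single result type")
    if format == "json":
        payload = {"schema_version": SCHEMA_VERSION, "records": [_to_jsonable(o) for o in objects]}
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    rows = []
    for obj in objects:
        d = _to_jsonable(obj)
        flat = {}
        for k, v in d.items():
            if isinstance(v, (dict, list)):
                flat[k] = json.dumps(v)
            else:
                flat[k] = v
                if isinstance(v, float):
                    flat[f"{k}_1dp"] = round(v, 1)
        rows.append(flat)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_results_json(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return payload["records"]
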