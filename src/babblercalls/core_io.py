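"""Domain types and tabular / GeoJSON input-output.

The analysis operates on five tabular inputs: group GPS fixes, located
loud-call events, individual life-history records, a pedigree, and daily
weighing sessions.  All coordinates are planar metres in a projected system
of the user's choosing (the study areas involved span only a few kilometres,
so any metric projection is equivalent at handheld-GPS accuracy).  Files are
delimited text with a header row; a *dialect* mapping lets callers rename
columns without rewriting files.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry


class ConfigurationError(ValueError):
    """A reader was configured inconsistently with the file (e.g. missing column)."""


class ParseError(ValueError):
    """A row could not be parsed; the message cites the 1-based data row."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


SEXES = ("male", "female", "unknown")
RANKS = ("dominant", "subordinate")


@dataclass(frozen=True)
class Fix:
    """One GPS fix of a whole group's position (recorded every 15 minutes)."""

    group_id: str
    timestamp: dt.datetime
    x: float
    y: float


@dataclass(frozen=True)
class CallRecord:
    """One located self-advertisement loud-call."""

    caller_id: str
    group_id: str
    timestamp: dt.datetime
    x: float
    y: float
    session_id: str = ""


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # male | female | unknown
    hatch_date: dt.date
    group_id: str
    rank: str  # dominant | subordinate

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"individual {self.id}: unknown sex {self.sex!r}")
        if self.rank not in RANKS:
            raise ValidationError(f"individual {self.id}: unknown rank {self.rank!r}")

    def age_days(self, on: dt.date) -> int:
        return (on - self.hatch_date).days

    def is_adult(self, on: dt.date, adult_age_days: int = 365) -> bool:
        """Adults are at least one year post-hatching (inclusive)."""
        return self.age_days(on) >= adult_age_days


class Pedigree:
    """Mapping individual id -> (dam id or None, sire id or None).

    Parents that appear only on the right-hand side are treated as founders.
    The pedigree must be acyclic; a topological order (parents before
    offspring) is computed on construction and reused by the relatedness
    recursion.
    """

    def __init__(self, parents: Mapping[str, tuple[str | None, str | None]]):
        self._parents: dict[str, tuple[str | None, str | None]] = {}
        for ind, (dam, sire) in parents.items():
            self._parents[str(ind)] = (
                None if dam in (None, "", "?") else str(dam),
                None if sire in (None, "", "?") else str(sire),
            )
        # implicit founders for parents without their own entry
        for dam, sire in list(self._parents.values()):
            for p in (dam, sire):
                if p is not None and p not in self._parents:
                    self._parents[p] = (None, None)
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        # Kahn's algorithm over parent -> offspring edges
        children: dict[str, list[str]] = {i: [] for i in self._parents}
        indeg: dict[str, int] = {i: 0 for i in self._parents}
        for ind, (dam, sire) in self._parents.items():
            for p in (dam, sire):
                if p is not None:
                    children[p].append(ind)
                    indeg[ind] += 1
        queue = sorted(i for i, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            node = queue.pop(0)
            order.append(node)
            for child in children[node]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
            queue.sort()
        if len(order) != len(self._parents):
            cyclic = sorted(set(self._parents) - set(order))
            raise ValidationError(f"pedigree contains a cycle involving {cyclic}")
        return order

    @property
    def ids(self) -> list[str]:
        return list(self._parents)

    @property
    def topological_order(self) -> list[str]:
        return list(self._order)

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        return self._parents.get(str(ind), (None, None))

    def __contains__(self, ind: object) -> bool:
        return ind in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self._parents == other._parents

    def as_mapping(self) -> dict[str, tuple[str | None, str | None]]:
        return dict(self._parents)


@dataclass(frozen=True)
class WeightSession:
    """One observation session with start and end body mass (grams)."""

    individual_id: str
    date: dt.date
    mass_start: float
    mass_end: float
    n_calling_bouts: int

    def __post_init__(self) -> None:
        if not (self.mass_start > 0 and self.mass_end > 0):
            raise ValidationError(
                f"weight session {self.individual_id}/{self.date}: masses must be positive"
            )
        if self.n_calling_bouts < 0:
            raise ValidationError(
                f"weight session {self.individual_id}/{self.date}: negative bout count"
            )

    @property
    def mass_change(self) -> float:
        """Daily weight change: end mass minus start mass, grams."""
        return self.mass_end - self.mass_start


@dataclass
class Dataset:
    fixes: list[Fix] = field(default_factory=list)
    calls: list[CallRecord] = field(default_factory=list)
    individuals: list[Individual] = field(default_factory=list)
    pedigree: Pedigree = field(default_factory=lambda: Pedigree({}))
    weights: list[WeightSession] = field(default_factory=list)

    def validate(self) -> None:
        """Check that all foreign identifiers resolve and per-type invariants hold."""
        ind_ids = {i.id for i in self.individuals}
        group_ids = {i.group_id for i in self.individuals}
        for c in self.calls:
            if c.caller_id not in ind_ids:
                raise ValidationError(f"call references unknown caller {c.caller_id!r}")
            if c.group_id not in group_ids:
                raise ValidationError(f"call references unknown group {c.group_id!r}")
        for w in self.weights:
            if w.individual_id not in ind_ids:
                raise ValidationError(
                    f"weight session references unknown individual {w.individual_id!r}"
                )
        for f in self.fixes:
            if not (math.isfinite(f.x) and math.isfinite(f.y)):
                raise ValidationError(f"non-finite fix coordinate for group {f.group_id}")
        # at most one dominant of each sex per group
        seen: set[tuple[str, str]] = set()
        for i in self.individuals:
            if i.rank == "dominant" and i.sex in ("male", "female"):
                key = (i.group_id, i.sex)
                if key in seen:
                    raise ValidationError(
                        f"group {i.group_id} has more than one dominant {i.sex}"
                    )
                seen.add(key)

    def individuals_by_group(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for i in self.individuals:
            out.setdefault(i.group_id, []).append(i)
        return out

    def fixes_by_group(self) -> dict[str, list[Fix]]:
        out: dict[str, list[Fix]] = {}
        for f in self.fixes:
            out.setdefault(f.group_id, []).append(f)
        return out

    def calls_by_caller(self) -> dict[str, list[CallRecord]]:
        out: dict[str, list[CallRecord]] = {}
        for c in self.calls:
            out.setdefault(c.caller_id, []).append(c)
        return out


# ---------------------------------------------------------------------------
# tabular readers


def _load_table(
    path: str | Path,
    required: Sequence[str],
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if dialect:
        # dialect maps logical name -> actual column name in the file
        rename = {actual: logical for logical, actual in dialect.items()}
        df = df.rename(columns=rename)
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: missing required column {col!r} (have {list(df.columns)})"
            )
    return df


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    probe = pd.to_numeric(df[col], errors="coerce")
    if probe.isna().any():
        row = int(probe.index[probe.isna()][0]) + 1  # 1-based data row
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row - 1]!r} in column {col!r} at data row {row}"
        )
    # correctly-rounded parse (pandas' fast parser is not round-trip exact)
    return pd.Series([float(v) for v in df[col]], index=df.index)


def _timestamps(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    ts = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(ts.index[ts.isna()][0]) + 1
        raise ParseError(f"{path}: unparseable timestamp in column {col!r} at data row {row}")
    return ts


def read_fixes(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[Fix]:
    """Read group GPS fixes, sorted by (group_id, timestamp)."""
    df = _load_table(path, ["group_id", "timestamp", "x", "y"], dialect, delimiter)
    df = df.assign(
        x=_numeric(df, "x", path),
        y=_numeric(df, "y", path),
        timestamp=_timestamps(df, "timestamp", path),
    )
    df = df.sort_values(["group_id", "timestamp"], kind="stable")
    return [
        Fix(str(r.group_id), r.timestamp.to_pydatetime(), float(r.x), float(r.y))
        for r in df.itertuples(index=False)
    ]


def read_calls(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[CallRecord]:
    df = _load_table(
        path, ["caller_id", "group_id", "timestamp", "x", "y"], dialect, delimiter
    )
    if "session_id" not in df.columns:
        df["session_id"] = ""
    df = df.assign(
        x=_numeric(df, "x", path),
        y=_numeric(df, "y", path),
        timestamp=_timestamps(df, "timestamp", path),
    )
    df = df.sort_values(["caller_id", "timestamp"], kind="stable")
    return [
        CallRecord(
            str(r.caller_id),
            str(r.group_id),
            r.timestamp.to_pydatetime(),
            float(r.x),
            float(r.y),
            str(r.session_id),
        )
        for r in df.itertuples(index=False)
    ]


def read_individuals(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[Individual]:
    df = _load_table(path, ["id", "sex", "hatch_date", "group_id", "rank"], dialect, delimiter)
    hatched = pd.to_datetime(df["hatch_date"], errors="coerce", format="ISO8601")
    if hatched.isna().any():
        row = int(hatched.index[hatched.isna()][0]) + 1
        raise ParseError(f"{path}: unparseable hatch_date at data row {row}")
    return [
        Individual(str(r.id), str(r.sex), h.date(), str(r.group_id), str(r.rank))
        for r, h in zip(df.itertuples(index=False), hatched)
    ]


def read_pedigree(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> Pedigree:
    """Three columns (id, dam, sire); '?' or empty marks an unknown parent."""
    df = _load_table(path, ["id", "dam", "sire"], dialect, delimiter)
    return Pedigree(
        {str(r.id): (str(r.dam), str(r.sire)) for r in df.itertuples(index=False)}
    )


def read_weights(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[WeightSession]:
    df = _load_table(
        path,
        ["individual_id", "date", "mass_start", "mass_end", "n_calling_bouts"],
        dialect,
        delimiter,
    )
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    if dates.isna().any():
        row = int(dates.index[dates.isna()][0]) + 1
        raise ParseError(f"{path}: unparseable date at data row {row}")
    start = _numeric(df, "mass_start", path)
    end = _numeric(df, "mass_end", path)
    bouts = _numeric(df, "n_calling_bouts", path)
    return [
        WeightSession(str(r.individual_id), d.date(), float(s), float(e), int(b))
        for r, d, s, e, b in zip(df.itertuples(index=False), dates, start, end, bouts)
    ]


def read_dataset(directory: str | Path, delimiter: str = ",") -> Dataset:
    """Read the five standard files (fixes/calls/individuals/pedigree/weights .csv)."""
    d = Path(directory)
    ds = Dataset(
        fixes=read_fixes(d / "fixes.csv", delimiter=delimiter),
        calls=read_calls(d / "calls.csv", delimiter=delimiter),
        individuals=read_individuals(d / "individuals.csv", delimiter=delimiter),
        pedigree=read_pedigree(d / "pedigree.csv", delimiter=delimiter),
        weights=read_weights(d / "weights.csv", delimiter=delimiter),
    )
    ds.validate()
    return ds


def write_dataset(dataset: Dataset, directory: str | Path, delimiter: str = ",") -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(f.group_id, f.timestamp.isoformat(), f.x, f.y) for f in dataset.fixes],
        columns=["group_id", "timestamp", "x", "y"],
    ).to_csv(d / "fixes.csv", index=False, sep=delimiter, float_format="%.17g")
    pd.DataFrame(
        [
            (c.caller_id, c.group_id, c.timestamp.isoformat(), c.x, c.y, c.session_id)
            for c in dataset.calls
        ],
        columns=["caller_id", "group_id", "timestamp", "x", "y", "session_id"],
    ).to_csv(d / "calls.csv", index=False, sep=delimiter, float_format="%.17g")
    pd.DataFrame(
        [
            (i.id, i.sex, i.hatch_date.isoformat(), i.group_id, i.rank)
            for i in dataset.individuals
        ],
        columns=["id", "sex", "hatch_date", "group_id", "rank"],
    ).to_csv(d / "individuals.csv", index=False, sep=delimiter)
    pd.DataFrame(
        [
            (ind, dam or "?", sire or "?")
            for ind, (dam, sire) in dataset.pedigree.as_mapping().items()
        ],
        columns=["id", "dam", "sire"],
    ).to_csv(d / "pedigree.csv", index=False, sep=delimiter)
    pd.DataFrame(
        [
            (w.individual_id, w.date.isoformat(), w.mass_start, w.mass_end, w.n_calling_bouts)
            for w in dataset.weights
        ],
        columns=["individual_id", "date", "mass_start", "mass_end", "n_calling_bouts"],
    ).to_csv(d / "weights.csv", index=False, sep=delimiter, float_format="%.17g")


# ---------------------------------------------------------------------------
# GeoJSON output


def write_polygons(
    polygons: Mapping[tuple[str, float], BaseGeometry],
    path: str | Path,
    extra_properties: Mapping[tuple[str, float], Mapping] | None = None,
) -> None:
    """Write isopleth polygons as a GeoJSON FeatureCollection.

    ``polygons`` maps (group_id, level) to a (multi)polygon in planar metres.
    Each feature carries ``group_id``, ``level`` and ``area_ha`` properties.
    """
    features = []
    for (group_id, level), geom in polygons.items():
        if not geom.is_valid:
            raise ValidationError(f"invalid polygon for ({group_id}, {level})")
        props = {
            "group_id": group_id,
            "level": float(level),
            "area_ha": geom.area / 10_000.0,
        }
        if extra_properties and (group_id, level) in extra_properties:
            props.update(extra_properties[(group_id, level)])
        features.append(
            {"type": "Feature", "geometry": geom_mapping(geom), "properties": props}
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=1))


def read_polygons(path: str | Path) -> dict[tuple[str, float], BaseGeometry]:
    """Inverse of :func:`write_polygons` (properties beyond the key are dropped)."""
    collection = json.loads(Path(path).read_text())
    out: dict[tuple[str, float], BaseGeometry] = {}
    for feature in collection.get("features", []):
        props = feature["properties"]
        out[(props["group_id"], float(props["level"]))] = geom_shape(feature["geometry"])
    return out
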