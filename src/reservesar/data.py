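"""Reserve richness tables: data model, CSV I/O and variable transformations.

The central object is a :class:`RichnessTable` — one row per protected area
(reserve) carrying geographic covariates (latitude, longitude, area in km²,
minimum/maximum/mean elevation and elevational range in m) and per-group
species richness counts.  Missing richness is a first-class state, distinct
from a genuine count of zero: a reserve may simply never have been surveyed
for a group.

Analyses operate on a :class:`GroupDataset`: the complete cases of one group
with the response and all predictors log10-transformed.  Counts or predictors
that can be exactly zero (a shoreline reserve has minimum elevation 0 m; a
reserve can hold zero dung beetles) are shifted by +1 before the log, as
controlled by :class:`TransformRules`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical beetle-group identifiers, in the order they are reported.
GROUPS = (
    "Carabidae",
    "Hydradephaga",
    "coprophagous_Scarabaeoidea",
    "phytophagous_Scarabaeoidea",
    "total_Scarabaeoidea",
    "Tenebrionidae",
)

#: The five trophic groups (total Scarabaeoidea duplicates its two subsets).
TROPHIC_GROUPS = (
    "Carabidae",
    "Hydradephaga",
    "coprophagous_Scarabaeoidea",
    "phytophagous_Scarabaeoidea",
    "Tenebrionidae",
)

#: Transformed predictor names, in canonical order.
PREDICTORS = (
    "log_area",
    "log_latitude",
    "log_elev_min",
    "log_elev_max",
    "log_elev_mean",
    "log_elev_range",
)

_RAW_OF_PREDICTOR = {
    "log_area": "area_km2",
    "log_latitude": "latitude",
    "log_elev_min": "elev_min_m",
    "log_elev_max": "elev_max_m",
    "log_elev_mean": "elev_mean_m",
    "log_elev_range": "elev_range_m",
}

#: Default logical-name → CSV-column map.
DEFAULT_SCHEMA = {
    "id": "id",
    "name": "name",
    "lat": "latitude",
    "lon": "longitude",
    "area_km2": "area_km2",
    "elev_min_m": "elev_min_m",
    "elev_max_m": "elev_max_m",
    "elev_range_m": "elev_range_m",
    "elev_mean_m": "elev_mean_m",
}

DEFAULT_MISSING_MARKERS = ("-", "")


@dataclass(frozen=True)
class ReserveRecord:
    """One reserve: identity, covariates and per-group richness.

    ``richness`` maps group name → non-negative count, or ``None`` when the
    group was never surveyed in this reserve (missing ≠ zero).
    """

    reserve_id: int
    name: str
    latitude: float
    longitude: float
    area_km2: float
    elev_min_m: float
    elev_max_m: float
    elev_range_m: float
    elev_mean_m: float
    richness: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.area_km2 > 0:
            raise ValueError(
                f"reserve {self.reserve_id}: area must be > 0, got {self.area_km2}"
            )
        if self.elev_max_m < self.elev_min_m:
            raise ValueError(
                f"reserve {self.reserve_id}: elev_max < elev_min"
            )
        for grp, val in self.richness.items():
            if val is not None and val < 0:
                raise ValueError(
                    f"reserve {self.reserve_id}: negative richness for {grp!r}"
                )


@dataclass(frozen=True)
class TransformRules:
    """log10 transformation policy for responses and predictors.

    ``plus_one_responses`` / ``plus_one_predictors`` name the variables that
    receive log10(x + 1) instead of log10(x), to accommodate exact zeros.
    """

    log_base: int = 10
    plus_one_responses: frozenset[str] = frozenset({"coprophagous_Scarabaeoidea"})
    plus_one_predictors: frozenset[str] = frozenset({"log_elev_min"})

    def __post_init__(self) -> None:
        if self.log_base != 10:
            raise ValueError("only decimal logarithms are supported")


DEFAULT_RULES = TransformRules()


@dataclass(frozen=True)
class RichnessTable:
    """An ordered collection of reserves sharing one group set."""

    records: tuple[ReserveRecord, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [r.reserve_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate reserve_id(s): {sorted(dupes)}")
        for r in self.records:
            if set(r.richness) != set(self.groups):
                raise ValueError(
                    f"reserve {r.reserve_id} does not carry the full group set"
                )

    def __len__(self) -> int:
        return len(self.records)

    def group_count(self, group: str) -> int:
        """Number of reserves with a non-missing count for ``group``."""
        self._check_group(group)
        return sum(1 for r in self.records if r.richness[group] is not None)

    def _check_group(self, group: str) -> None:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}; have {list(self.groups)}")

    def to_frame(self) -> pd.DataFrame:
        """Materialise as a DataFrame (missing richness → NaN)."""
        rows = []
        for r in self.records:
            row = {
                "id": r.reserve_id,
                "name": r.name,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "area_km2": r.area_km2,
                "elev_min_m": r.elev_min_m,
                "elev_max_m": r.elev_max_m,
                "elev_range_m": r.elev_range_m,
                "elev_mean_m": r.elev_mean_m,
            }
            for g in self.groups:
                v = r.richness[g]
                row[f"richness.{g}"] = np.nan if v is None else v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupDataset:
    """Complete cases of one group, log10-transformed and fit-ready.

    ``response`` is log10 richness (log10(S+1) for plus-one groups);
    ``predictors`` holds the transformed covariate columns of
    :data:`PREDICTORS`; ``raw`` keeps the untransformed values for
    traceability, indexed like ``reserve_ids``.
    """

    group: str
    reserve_ids: tuple[int, ...]
    response: np.ndarray
    predictors: Mapping[str, np.ndarray]
    raw: pd.DataFrame
    plus_one_response: bool
    transformed: bool = True

    @property
    def n(self) -> int:
        return len(self.response)

    def __post_init__(self) -> None:
        for name, col in self.predictors.items():
            if len(col) != self.n:
                raise ValueError(f"predictor {name!r} length mismatch")

    def predictor_matrix(self, names: Sequence[str]) -> dict[str, np.ndarray]:
        return {name: np.asarray(self.predictors[name]) for name in names}


def _parse_cell(value, markers: tuple[str, ...]):
    if value is None:
        return None
    s = str(value).strip()
    if s in markers or s.lower() == "nan":
        return None
    x = float(s)
    if x != int(x):
        raise ValueError(f"richness must be an integer count, got {s!r}")
    return int(x)


def load_richness_table(
    source,
    schema: Mapping[str, str] | None = None,
    *,
    missing_markers: Iterable[str] = DEFAULT_MISSING_MARKERS,
    delimiter: str = ",",
    elev_range_tol: float = 0.5,
) -> RichnessTable:
    """Read a per-reserve richness CSV into a :class:`RichnessTable`.

    ``source`` is a path or text stream.  ``schema`` maps the logical column
    names of :data:`DEFAULT_SCHEMA` to the actual header names; any column
    named ``richness.<group>`` is taken as a richness column.  Cells equal to
    one of ``missing_markers`` (default ``"-"`` and blank) parse as MISSING.

    A mismatch between the stated elevational range and max − min is reported
    as a warning, not an error: some sources report sampling-point elevations
    compiled from different references.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    markers = tuple(str(m) for m in missing_markers)
    df = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError("no records")

    rich_cols = [c for c in df.columns if c.startswith("richness.")]
    if not rich_cols:
        raise ValueError("no richness.<group> columns found")
    groups = tuple(c.split(".", 1)[1] for c in rich_cols)

    def num(row, logical, optional=False):
        col = schema[logical]
        s = str(row[col]).strip() if col in row else ""
        if s in markers:
            if optional:
                return None
            raise ValueError(f"missing required value for {logical!r}")
        return float(s)

    records = []
    for idx, row in df.iterrows():
        rid_raw = str(row[schema["id"]]).strip()
        try:
            rid = int(float(rid_raw))
        except ValueError as exc:
            raise ValueError(f"row {idx}: unparseable reserve id {rid_raw!r}") from exc
        richness = {}
        for col, grp in zip(rich_cols, groups):
            try:
                richness[grp] = _parse_cell(row[col], markers)
            except ValueError as exc:
                raise ValueError(f"row {idx} (reserve {rid}): {exc}") from exc
        try:
            rec = ReserveRecord(
                reserve_id=rid,
                name=str(row.get(schema["name"], rid)),
                latitude=num(row, "lat"),
                longitude=num(row, "lon"),
                area_km2=num(row, "area_km2"),
                elev_min_m=num(row, "elev_min_m"),
                elev_max_m=num(row, "elev_max_m"),
                elev_range_m=num(row, "elev_range_m"),
                elev_mean_m=num(row, "elev_mean_m"),
                richness=richness,
            )
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        expected = rec.elev_max_m - rec.elev_min_m
        if abs(rec.elev_range_m - expected) > elev_range_tol:
            warnings.warn(
                f"reserve {rid}: elev_range_m = {rec.elev_range_m} differs from "
                f"elev_max - elev_min = {expected}",
                stacklevel=2,
            )
        records.append(rec)

    return RichnessTable(records=tuple(records), groups=groups)


def load_italian_reserves(elevation_set: str = "default") -> RichnessTable:
    """Load the packaged 23-reserve Italian beetle-richness fixture.

    The fixture was transcribed from published faunal surveys of Italian
    protected areas: 23 reserves spanning four orders of magnitude in area
    (0.17–1700 km²) and the full Italian latitudinal gradient, with richness
    for six beetle groups (five trophic groups plus total Scarabaeoidea).

    For reserve 8 (Foreste Casentinesi) two elevation sets exist because the
    carabid and water-beetle surveys sampled different points;
    ``elevation_set="hydradephaga"`` selects the water-beetle sampling
    elevations, ``"default"`` the carabid ones.
    """
    if elevation_set not in ("default", "hydradephaga"):
        raise ValueError("elevation_set must be 'default' or 'hydradephaga'")
    ref = resources.files("reservesar.fixtures") / "italian_reserves.csv"
    with ref.open("r", encoding="utf-8") as fh:
        table = load_richness_table(fh)
    if elevation_set == "hydradephaga":
        with ref.open("r", encoding="utf-8") as fh:
            alt = pd.read_csv(fh)
        recs = []
        for rec in table.records:
            row = alt.loc[alt["id"] == rec.reserve_id].iloc[0]
            if not pd.isna(row.get("elev_min_m_alt", np.nan)):
                rec = replace(
                    rec,
                    elev_min_m=float(row["elev_min_m_alt"]),
                    elev_max_m=float(row["elev_max_m_alt"]),
                    elev_range_m=float(row["elev_range_m_alt"]),
                    elev_mean_m=float(row["elev_mean_m_alt"]),
                )
            recs.append(rec)
        table = RichnessTable(records=tuple(recs), groups=table.groups)
    return table


def subset_group(
    table: RichnessTable,
    group: str,
    rules: TransformRules = DEFAULT_RULES,
    *,
    exclude_ids: Iterable[int] = (),
) -> GroupDataset:
    """Extract one group's complete cases and apply the log10 transforms.

    Rows where this group's richness is MISSING are dropped (other groups'
    missingness is irrelevant); ``exclude_ids`` removes further reserves by
    id, e.g. to match a published fit that used a subset of the table.
    """
    table._check_group(group)
    excl = set(exclude_ids)
    recs = [
        r
        for r in table.records
        if r.richness[group] is not None and r.reserve_id not in excl
    ]
    if len(recs) < 3:
        raise ValueError(
            f"group {group!r}: only {len(recs)} complete cases; need >= 3"
        )

    counts = np.array([float(r.richness[group]) for r in recs])
    plus_one = group in rules.plus_one_responses
    if not plus_one and (counts == 0).any():
        raise ValueError(
            f"group {group!r} has zero counts but no plus-one rule; "
            "log10(0) undefined"
        )
    response = np.log10(counts + 1.0) if plus_one else np.log10(counts)

    raw = pd.DataFrame(
        {
            "reserve_id": [r.reserve_id for r in recs],
            "richness": counts,
            "area_km2": [r.area_km2 for r in recs],
            "latitude": [r.latitude for r in recs],
            "elev_min_m": [r.elev_min_m for r in recs],
            "elev_max_m": [r.elev_max_m for r in recs],
            "elev_mean_m": [r.elev_mean_m for r in recs],
            "elev_range_m": [r.elev_range_m for r in recs],
        }
    )
    predictors = {}
    for pname in PREDICTORS:
        col = raw[_RAW_OF_PREDICTOR[pname]].to_numpy(dtype=float)
        if pname in rules.plus_one_predictors:
            predictors[pname] = np.log10(col + 1.0)
        else:
            if (col <= 0).any():
                raise ValueError(
                    f"predictor {pname!r} has non-positive values and no "
                    "plus-one rule"
                )
            predictors[pname] = np.log10(col)

    return GroupDataset(
        group=group,
        reserve_ids=tuple(int(r.reserve_id) for r in recs),
        response=response,
        predictors=predictors,
        raw=raw,
        plus_one_response=plus_one,
    )


def write_table(result, sink, *, sep: str = ",", missing_marker: str = "-") -> None:
    """Write a :class:`RichnessTable` or DataFrame to a CSV/TSV sink.

    Full precision is stored; display rounding is left to presentation
    layers.  Round-trips through :func:`load_richness_table` without loss.
    """
    if isinstance(result, RichnessTable):
        frame = result.to_frame()
        rich_cols = [c for c in frame.columns if c.startswith("richness.")]
        frame[rich_cols] = frame[rich_cols].astype(object)
        frame = frame.fillna({c: missing_marker for c in rich_cols})
    elif isinstance(result, pd.DataFrame):
        frame = result
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    if frame.empty:
        raise ValueError("refusing to write an empty result")
    frame.to_csv(sink, sep=sep, index=False)
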