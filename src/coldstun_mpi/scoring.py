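"""Mortality-prediction-index (MPI) band tables and scoring.

An MPI is a point-based severity score: each blood analyte has bands of
abnormal values on the high and/or low side of a normal gap, each band worth
a fixed point penalty that grows toward the extreme; an animal's index score
is the sum of its per-analyte points.  Three initial tables exist:

* MPI1 -- pH, pCO2, sodium, potassium (points 2/4/6/8)
* MPI2 -- glucose, pH, pCO2, pO2, sodium, potassium, ionized calcium (1-4)
* MPI3 -- MPI2's analytes plus anion gap, osmolality, bicarbonate, chloride
  (points 2/4/6/8)

The refined indices keep only the analytes whose standalone discrimination
of 7-day mortality reached AUC >= 0.7, and attach a decision cut-off:

* MPI4 = {pH, pCO2, potassium} from the MPI1 table, deranged at score >= 10
* MPI5 = {pH, pCO2, pO2, potassium} from the MPI2 table, deranged at >= 6
* MPI6 = {pH, pO2, potassium} from the MPI3 table, deranged at >= 8

Band tables ship as a versioned JSON resource and can be overridden by path;
a table violating its structural invariants is refused at load time.

Conventions: printed ranges "a-b" are closed [a, b]; ">=a" is [a, inf);
"<b" is open at b.  A value on the shared endpoint of two bands takes the
higher points (conservative for triage).  Values falling in no band -- the
normal gap, or a gap between printed bands -- score 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError, ScoringError, UnknownAnalyteError
from .panels import ANALYTES, BloodPanel

DERANGED = "deranged"
STABLE = "stable"


@dataclass(frozen=True)
class ScoreBand:
    """One analyte interval mapped to a point penalty.

    ``low``/``high`` of ``None`` mean unbounded; ``*_open`` marks an open
    endpoint.  ``side`` records whether the band lies above ("high") or below
    ("low") the analyte's normal gap.
    """

    analyte: str
    side: str  # "high" | "low"
    low: Optional[float]
    high: Optional[float]
    points: int
    low_open: bool = False
    high_open: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ConfigurationError(f"band references unknown analyte {self.analyte!r}")
        if self.side not in ("high", "low"):
            raise ConfigurationError(f"band side must be 'high' or 'low', got {self.side!r}")
        if self.points <= 0:
            raise ConfigurationError(f"band points must be positive, got {self.points}")
        if self.low is not None and self.high is not None:
            if self.low > self.high or (
                self.low == self.high and (self.low_open or self.high_open)
            ):
                raise ConfigurationError(
                    f"empty band interval for {self.analyte}: "
                    f"({self.low}, {self.high})"
                )

    def contains(self, value: float) -> bool:
        if self.low is not None:
            if value < self.low or (self.low_open and value == self.low):
                return False
        if self.high is not None:
            if value > self.high or (self.high_open and value == self.high):
                return False
        return True


@dataclass(frozen=True)
class ScoringTable:
    """All bands of one index table (MPI1, MPI2 or MPI3), grouped by analyte."""

    table_id: str
    bands: tuple[ScoreBand, ...]
    point_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        by_key: dict[tuple[str, str], list[ScoreBand]] = {}
        for b in self.bands:
            if b.points not in self.point_columns:
                raise ConfigurationError(
                    f"{self.table_id}: band {b.analyte} {b.side} has points "
                    f"{b.points}, not in the table's columns {self.point_columns}"
                )
            by_key.setdefault((b.analyte, b.side), []).append(b)
        for (analyte, side), group in by_key.items():
            # order bands from the normal gap outward; severity (points)
            # must strictly increase toward the extreme
            if side == "high":
                ordered = sorted(
                    group, key=lambda b: -math.inf if b.low is None else b.low
                )
            else:
                ordered = sorted(
                    group,
                    key=lambda b: math.inf if b.high is None else b.high,
                    reverse=True,
                )
            pts = [b.points for b in ordered]
            if any(p2 <= p1 for p1, p2 in zip(pts, pts[1:])):
                raise ConfigurationError(
                    f"{self.table_id}: {analyte} {side}-side points {pts} do not "
                    "strictly increase toward the extreme"
                )
        # within one analyte, adjacent bands may touch at a shared endpoint
        # but must not overlap on an interval of positive length
        by_analyte: dict[str, list[ScoreBand]] = {}
        for b in self.bands:
            by_analyte.setdefault(b.analyte, []).append(b)
        for analyte, group in by_analyte.items():
            spans = sorted(group, key=lambda b: -math.inf if b.low is None else b.low)
            for a, b in zip(spans, spans[1:]):
                a_hi = math.inf if a.high is None else a.high
                b_lo = -math.inf if b.low is None else b.low
                if b_lo < a_hi:
                    raise ConfigurationError(
                        f"{self.table_id}: {analyte} bands overlap beyond a "
                        f"shared endpoint near {b_lo}"
                    )

    @property
    def analytes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(b.analyte, None)
        return tuple(seen)

    def bands_for(self, analyte: str) -> tuple[ScoreBand, ...]:
        group = tuple(b for b in self.bands if b.analyte == analyte)
        if not group:
            raise UnknownAnalyteError(
                f"table {self.table_id} has no bands for analyte {analyte!r}"
            )
        return group

    def max_points(self, analytes: Optional[Sequence[str]] = None) -> int:
        names = self.analytes if analytes is None else analytes
        return sum(max(b.points for b in self.bands_for(a)) for a in names)


@dataclass(frozen=True)
class IndexDefinition:
    """A named index: source table, analyte subset, optional decision cut-off."""

    index_id: str
    source_table: str
    analytes: tuple[str, ...]
    cutoff: Optional[int] = None


#: MPI1-3 score every analyte of their table and carry no fixed cut-off;
#: MPI4-6 are the AUC-refined subsets with their published cut-offs.
INDEX_DEFINITIONS: Mapping[str, IndexDefinition] = {
    "MPI1": IndexDefinition("MPI1", "MPI1", ("pH", "pCO2", "sodium", "potassium")),
    "MPI2": IndexDefinition(
        "MPI2",
        "MPI2",
        ("glucose", "pH", "pCO2", "pO2", "sodium", "potassium", "ionized_calcium"),
    ),
    "MPI3": IndexDefinition(
        "MPI3",
        "MPI3",
        (
            "glucose",
            "pH",
            "pCO2",
            "pO2",
            "sodium",
            "potassium",
            "ionized_calcium",
            "anion_gap",
            "osmolality",
            "bicarbonate",
            "chloride",
        ),
    ),
    "MPI4": IndexDefinition("MPI4", "MPI1", ("pH", "pCO2", "potassium"), cutoff=10),
    "MPI5": IndexDefinition("MPI5", "MPI2", ("pH", "pCO2", "pO2", "potassium"), cutoff=6),
    "MPI6": IndexDefinition("MPI6", "MPI3", ("pH", "pO2", "potassium"), cutoff=8),
}


def get_index(index_id: str) -> IndexDefinition:
    try:
        return INDEX_DEFINITIONS[index_id.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unknown index {index_id!r}; expected one of {sorted(INDEX_DEFINITIONS)}"
        ) from None


class BandTableSet:
    """The loaded band-table resource: tables keyed by id, plus its version."""

    def __init__(self, tables: Mapping[str, ScoringTable], version: str):
        self.tables = dict(tables)
        self.version = version

    def __getitem__(self, table_id: str) -> ScoringTable:
        try:
            return self.tables[table_id]
        except KeyError:
            raise ConfigurationError(
                f"no band table {table_id!r}; available: {sorted(self.tables)}"
            ) from None

    def table_for(self, index: IndexDefinition) -> ScoringTable:
        table = self[index.source_table]
        missing = [a for a in index.analytes if a not in table.analytes]
        if missing:
            raise ConfigurationError(
                f"index {index.index_id} requires analytes {missing} absent "
                f"from table {table.table_id}"
            )
        return table


_DEFAULT_TABLES: Optional[BandTableSet] = None


def load_band_tables(path: str | Path | None = None) -> BandTableSet:
    """Load band tables from JSON (packaged resource when ``path`` is None)."""
    if path is None:
        text = resources.files("coldstun_mpi.data").joinpath("band_tables.json").read_text()
    else:
        text = Path(path).read_text()
    doc = json.loads(text)
    tables = {}
    for table_id, raw_bands in doc["tables"].items():
        bands = tuple(
            ScoreBand(
                analyte=b["analyte"],
                side=b["side"],
                low=b["low"],
                high=b["high"],
                points=int(b["points"]),
                low_open=bool(b.get("low_open", False)),
                high_open=bool(b.get("high_open", False)),
            )
            for b in raw_bands
        )
        tables[table_id] = ScoringTable(
            table_id=table_id,
            bands=bands,
            point_columns=tuple(doc["point_columns"][table_id]),
        )
    return BandTableSet(tables, version=str(doc.get("version", "unversioned")))


def default_band_tables() -> BandTableSet:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_band_tables()
    return _DEFAULT_TABLES


def score_analyte(table: ScoringTable, analyte: str, value: float) -> int:
    """Points for one analyte value: the containing band's points, 0 in a gap.

    On a shared boundary of two bands the higher points win.
    """
    if not math.isfinite(value):
        raise ScoringError(f"{analyte}: value must be finite, got {value!r}")
    return max((b.points for b in table.bands_for(analyte) if b.contains(value)), default=0)


def score_index(
    index: IndexDefinition | str,
    panel: BloodPanel,
    tables: Optional[BandTableSet] = None,
) -> int:
    """Total index score: the sum of per-analyte points over the index's analytes."""
    if isinstance(index, str):
        index = get_index(index)
    tables = tables or default_band_tables()
    table = tables.table_for(index)
    total = 0
    for analyte in index.analytes:
        value = panel.get(analyte)
        if value is None:
            raise ScoringError(
                f"panel {panel.animal_id!r} is missing analyte {analyte!r} "
                f"required by {index.index_id}"
            )
        total += score_analyte(table, analyte, value)
    return total


def classify(
    index: IndexDefinition | str,
    panel: BloodPanel,
    cutoff: Optional[int] = None,
    tables: Optional[BandTableSet] = None,
) -> str:
    """Categorise a panel as ``deranged`` (score >= cut-off) or ``stable``."""
    if isinstance(index, str):
        index = get_index(index)
    effective = cutoff if cutoff is not None else index.cutoff
    if effective is None:
        raise ConfigurationError(
            f"index {index.index_id} has no decision cut-off; pass one explicitly"
        )
    return DERANGED if score_index(index, panel, tables) >= effective else STABLE
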