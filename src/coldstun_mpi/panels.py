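"""The admission blood panel: the object every score consumes.

A :class:`BloodPanel` holds one animal's temperature-corrected blood-gas and
chemistry values at admission plus the binary 7-day outcome when known.  Any
analyte may be absent; derived analytes (bicarbonate, anion gap) can be
computed on demand from their inputs, with measured values always taking
precedence over computed ones.

Panels interchange as CSV with a fixed header (see :data:`CSV_COLUMNS`); a
mismatched header is an error, never a guess, because a silently mis-mapped
unit column would corrupt every downstream score.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import bloodgas
from .errors import DomainError, PanelCSVError

#: Canonical analyte names, in panel-CSV column order.
ANALYTES = (
    "pH",
    "pCO2",
    "pO2",
    "sodium",
    "potassium",
    "chloride",
    "ionized_calcium",
    "glucose",
    "osmolality",
    "anion_gap",
    "bicarbonate",
)

#: CSV header -> BloodPanel field.  The header carries the units contract:
#: mmol/l for electrolytes and glucose, mmHg for partial pressures, mOsm/kg
#: for osmolality, degC for body temperature.  No unit auto-conversion.
CSV_COLUMNS = {
    "animal_id": "animal_id",
    "body_temp_C": "body_temp",
    "pH": "pH",
    "pCO2_mmHg": "pCO2",
    "pO2_mmHg": "pO2",
    "Na_mmol_L": "sodium",
    "K_mmol_L": "potassium",
    "Cl_mmol_L": "chloride",
    "iCa_mmol_L": "ionized_calcium",
    "glucose_mmol_L": "glucose",
    "osmolality_mOsm_kg": "osmolality",
    "anion_gap_mmol_L": "anion_gap",
    "HCO3_mmol_L": "bicarbonate",
    "outcome_died7d": "outcome",
}

BODY_TEMP_WINDOW = (0.0, 40.0)

# anion_gap is a difference of concentrations and may legitimately be small
# or negative; everything else here is a concentration or partial pressure.
_NONNEGATIVE = set(ANALYTES) - {"pH", "anion_gap"}


@dataclass(frozen=True)
class BloodPanel:
    """One animal's admission analytes (temperature-corrected) and outcome.

    ``outcome`` is 1 if the animal died naturally within 7 days of admission,
    0 if it survived that window, ``None`` if unknown.
    """

    animal_id: str
    body_temp: Optional[float] = None
    pH: Optional[float] = None
    pCO2: Optional[float] = None
    pO2: Optional[float] = None
    sodium: Optional[float] = None
    potassium: Optional[float] = None
    chloride: Optional[float] = None
    ionized_calcium: Optional[float] = None
    glucose: Optional[float] = None
    osmolality: Optional[float] = None
    anion_gap: Optional[float] = None
    bicarbonate: Optional[float] = None
    outcome: Optional[int] = None

    def __post_init__(self) -> None:
        for name in _NONNEGATIVE:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(
                    f"panel {self.animal_id!r}: {name} must be >= 0, got {v}"
                )
        if self.pH is not None and not (
            bloodgas.PH_WINDOW[0] <= self.pH <= bloodgas.PH_WINDOW[1]
        ):
            raise DomainError(
                f"panel {self.animal_id!r}: pH {self.pH} outside sanity "
                f"window {bloodgas.PH_WINDOW}"
            )
        if self.body_temp is not None and not (
            BODY_TEMP_WINDOW[0] <= self.body_temp <= BODY_TEMP_WINDOW[1]
        ):
            raise DomainError(
                f"panel {self.animal_id!r}: body temperature {self.body_temp} "
                f"outside sanity window {BODY_TEMP_WINDOW}"
            )
        if self.outcome is not None and self.outcome not in (0, 1):
            raise DomainError(
                f"panel {self.animal_id!r}: outcome must be 0, 1 or absent, "
                f"got {self.outcome!r}"
            )

    def get(self, analyte: str) -> Optional[float]:
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}")
        return getattr(self, analyte)

    def is_scoreable_for(self, analytes: Iterable[str]) -> bool:
        """True iff every analyte in ``analytes`` is present."""
        return all(self.get(a) is not None for a in analytes)

    def with_derived(
        self,
        coeffs: Optional[bloodgas.CorrectionCoefficients] = None,
        include_potassium: bool = True,
    ) -> "BloodPanel":
        """Fill in missing derived analytes where their inputs are present.

        Bicarbonate comes from Henderson-Hasselbalch (needs pH, pCO2, body
        temperature and a coefficient set); the anion gap from the four-ion
        difference.  Measured values are never overwritten.
        """
        updates: dict[str, float] = {}
        bicarb = self.bicarbonate
        if (
            bicarb is None
            and coeffs is not None
            and self.pH is not None
            and self.pCO2 is not None
            and self.body_temp is not None
        ):
            bicarb = bloodgas.calc_bicarbonate(self.pH, self.pCO2, coeffs, self.body_temp)
            updates["bicarbonate"] = bicarb
        if (
            self.anion_gap is None
            and bicarb is not None
            and self.sodium is not None
            and self.potassium is not None
            and self.chloride is not None
        ):
            updates["anion_gap"] = bloodgas.calc_anion_gap(
                self.sodium, self.potassium, self.chloride, bicarb, include_potassium
            )
        return replace(self, **updates) if updates else self


_FIELD_NAMES = {f.name for f in fields(BloodPanel)}


def _parse_cell(text: str, column: str, row_num: int):
    text = text.strip()
    if text == "":
        return None
    field = CSV_COLUMNS[column]
    try:
        if field == "outcome":
            if text not in ("0", "1"):
                raise ValueError("outcome must be 0, 1 or empty")
            return int(text)
        return float(text)
    except ValueError as exc:
        raise PanelCSVError(
            f"row {row_num}, column {column!r}: cannot parse {text!r} ({exc})"
        ) from exc


def read_panels(path: str | Path) -> list[BloodPanel]:
    """Read a panel CSV (strict fixed header) into BloodPanel objects."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelCSVError(f"{path}: empty file") from None
        expected = list(CSV_COLUMNS)
        unknown = [c for c in header if c not in CSV_COLUMNS]
        missing = [c for c in expected if c not in header]
        if unknown or missing:
            raise PanelCSVError(
                f"{path}: bad header; unknown columns {unknown}, "
                f"missing columns {missing}; expected exactly {expected}"
            )
        panels = []
        for row_num, row in enumerate(reader, start=2):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            if len(row) != len(header):
                raise PanelCSVError(
                    f"row {row_num}: expected {len(header)} cells, got {len(row)}"
                )
            values: dict = {}
            for column, cell in zip(header, row):
                field = CSV_COLUMNS[column]
                if field == "animal_id":
                    if cell.strip() == "":
                        raise PanelCSVError(
                            f"row {row_num}, column 'animal_id': must not be empty"
                        )
                    values[field] = cell.strip()
                else:
                    values[field] = _parse_cell(cell, column, row_num)
            panels.append(BloodPanel(**values))
    return panels


def write_panels(panels: Sequence[BloodPanel], path: str | Path) -> None:
    """Write panels as CSV with the canonical header, at full float precision."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(CSV_COLUMNS))
        for panel in panels:
            row = []
            for column, field in CSV_COLUMNS.items():
                v = getattr(panel, field)
                if v is None:
                    row.append("")
                elif field == "animal_id":
                    row.append(v)
                elif field == "outcome":
                    row.append(str(int(v)))
                else:
                    row.append(repr(float(v)))
            writer.writerow(row)
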