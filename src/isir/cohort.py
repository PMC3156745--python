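"""Patient cohort data model, CSV/config reading, and validation.

A cohort is a flat table: one row per patient, with a positive survival time in
months, an event flag (1 = death observed, 0 = censored at that time), and one
integer column per ordinal covariate (TNM stage components, histology, and
semi-quantitative immunostaining grades). Each covariate's admissible values are
declared in a variable-spec file; the count of admissible values is the scale
divisor used when covariates on different scales are combined into one score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

RESERVED_COLUMNS = ("patient_id", "survival_time", "event")


@dataclass(frozen=True)
class VariableSpec:
    """An ordinal covariate: its admissible integer values and scale divisor.

    The divisor is the number of possible realizations (2 for binary variables
    such as metastasis status or histology, 4 for staining grades and T stage)
    and is what the covariate is divided by when entering the composite score.
    """

    name: str
    admissible_values: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.admissible_values)
        if len(vals) < 2:
            raise ValidationError(f"variable {self.name!r} needs >= 2 admissible values")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                f"admissible values for {self.name!r} must be strictly increasing"
            )
        object.__setattr__(self, "admissible_values", vals)

    @property
    def divisor(self) -> int:
        return len(self.admissible_values)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifier, follow-up time (months), event flag, covariates."""

    patient_id: str
    survival_time: float
    event: int
    covariates: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.survival_time > 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: survival_time must be > 0, "
                f"got {self.survival_time}"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: event must be 0 or 1, got {self.event}"
            )


@dataclass
class Cohort:
    """A validated list of patients plus the variable specs they conform to."""

    patients: list[PatientRecord]
    variables: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dupes}")
        spec_by_name = {s.name: s for s in self.variables}
        for p in self.patients:
            for name, value in p.covariates.items():
                spec = spec_by_name.get(name)
                if spec is None:
                    raise ValidationError(
                        f"patient {p.patient_id!r}: covariate {name!r} has no "
                        "variable spec"
                    )
                if value not in spec.admissible_values:
                    raise ValidationError(
                        f"patient {p.patient_id!r}: value {value} not admissible "
                        f"for variable {name!r} (allowed {spec.admissible_values})"
                    )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.variables]

    def spec(self, name: str) -> VariableSpec:
        for s in self.variables:
            if s.name == name:
                return s
        raise KeyError(name)

    def column(self, name: str) -> list[int]:
        """Covariate values in patient order."""
        return [p.covariates[name] for p in self.patients]

    @property
    def survival_times(self) -> list[float]:
        return [p.survival_time for p in self.patients]

    @property
    def events(self) -> list[int]:
        return [p.event for p in self.patients]

    def drop(self, patient_id: str) -> "Cohort":
        """Cohort with one patient removed (used by leave-one-out folds)."""
        kept = [p for p in self.patients if p.patient_id != patient_id]
        if len(kept) == len(self.patients):
            raise KeyError(patient_id)
        return Cohort(kept, self.variables)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row: dict = {
                "patient_id": p.patient_id,
                "survival_time": p.survival_time,
                "event": p.event,
            }
            row.update({s.name: p.covariates[s.name] for s in self.variables})
            rows.append(row)
        return pd.DataFrame(rows)


def read_variable_specs(path: str | Path) -> list[VariableSpec]:
    """Read a JSON or YAML mapping of variable name -> admissible values."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or not raw:
        raise FormatError(f"{path}: expected a non-empty mapping of name -> values")
    return [VariableSpec(str(name), tuple(values)) for name, values in raw.items()]


def read_cohort(path: str | Path, spec_path: str | Path) -> Cohort:
    """Read and validate a cohort CSV against a variable-spec file.

    The CSV must carry the columns patient_id, survival_time, event, and one
    integer column per declared variable. Rows with missing values in any
    declared variable are rejected outright — with cohorts of a few dozen
    patients, silent imputation would corrupt every downstream correlation.
    """
    specs = read_variable_specs(spec_path)
    df = pd.read_csv(path)
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    missing += [s.name for s in specs if s.name not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df[[s.name for s in specs] + list(RESERVED_COLUMNS)].isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(
            f"{path}: missing values in column(s) {bad}; rows with missing "
            "covariates are not accepted"
        )
    patients = []
    for _, row in df.iterrows():
        patients.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                survival_time=float(row["survival_time"]),
                event=int(row["event"]),
                covariates={s.name: int(row[s.name]) for s in specs},
            )
        )
    return Cohort(patients, specs)


def write_cohort(cohort: Cohort, path: str | Path, spec_path: str | Path | None = None) -> None:
    """Write a cohort back to CSV (and optionally its variable specs to JSON)."""
    cohort.to_frame().to_csv(path, index=False)
    if spec_path is not None:
        mapping = {s.name: list(s.admissible_values) for s in cohort.variables}
        Path(spec_path).write_text(json.dumps(mapping, indent=1), encoding="utf-8")


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write a result table (list of uniform dicts or a DataFrame) to CSV."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if not rows:
            raise FormatError("write_table: empty table")
        cols = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != cols:
                raise FormatError("write_table: non-uniform columns across rows")
        df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        raise FormatError("write_table: empty table")
    df.to_csv(path, index=False)


def cohort_from_arrays(
    times: Iterable[float],
    events: Iterable[int],
    covariates: Mapping[str, Iterable[int]],
    specs: Iterable[VariableSpec],
) -> Cohort:
    """Assemble a cohort from parallel arrays (simulation and test helper)."""
    specs = list(specs)
    times = list(times)
    events = list(events)
    cols = {k: list(v) for k, v in covariates.items()}
    patients = [
        PatientRecord(
            patient_id=f"P{i + 1:04d}",
            survival_time=float(times[i]),
            event=int(events[i]),
            covariates={k: int(cols[k][i]) for k in cols},
        )
        for i in range(len(times))
    ]
    return Cohort(patients, specs)
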