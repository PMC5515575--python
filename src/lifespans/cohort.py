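"""Per-animal lifespan records and validated cohorts.

The on-disk contract is a plain CSV with columns
``animal_id, age_days, genotype, treatment, sex, event``; ``event`` is
optional on input and defaults to True (an observed death) because rodent
longevity studies typically follow every animal to death. Ages are stored in
days as reals: day-resolution data are expected but sub-day simulated times
are kept exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError, SchemaError

GENOTYPES = ("dwarf", "control")
TREATMENTS = ("GH", "saline")
SEXES = ("male", "female")

REQUIRED_COLUMNS = ("animal_id", "age_days", "genotype", "treatment", "sex")
ALL_COLUMNS = REQUIRED_COLUMNS + ("event",)


@dataclass(frozen=True)
class LifespanRecord:
    """One animal: age at death (or censoring) in days plus design labels."""

    animal_id: str
    age_days: float
    genotype: str
    treatment: str
    sex: str
    event: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_days) or self.age_days <= 0:
            raise CohortValidationError(
                f"age_days must be a positive finite number, got {self.age_days!r} "
                f"for animal {self.animal_id!r}"
            )
        for name, value, allowed in (
            ("genotype", self.genotype, GENOTYPES),
            ("treatment", self.treatment, TREATMENTS),
            ("sex", self.sex, SEXES),
        ):
            if value not in allowed:
                raise CohortValidationError(
                    f"unknown {name} label {value!r} for animal "
                    f"{self.animal_id!r}; expected one of {allowed}"
                )

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.genotype, self.treatment, self.sex)


@dataclass(frozen=True)
class Cohort:
    """An ordered, validated collection of :class:`LifespanRecord`.

    Animal ids must be unique; the cohort is never empty. ``protocol_label``
    is free text naming the treatment protocol (e.g. ``"week1"``).
    """

    records: tuple[LifespanRecord, ...]
    protocol_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise CohortValidationError("cohort must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.animal_id in seen:
                raise CohortValidationError(
                    f"duplicate animal_id {rec.animal_id!r} in cohort"
                )
            seen.add(rec.animal_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LifespanRecord]:
        return iter(self.records)

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age_days for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=bool)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in self.records],
                "age_days": [r.age_days for r in self.records],
                "genotype": [r.genotype for r in self.records],
                "treatment": [r.treatment for r in self.records],
                "sex": [r.sex for r in self.records],
                "event": [r.event for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, protocol_label: str = "") -> "Cohort":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for idx, row in enumerate(df.itertuples(index=False)):
            raw_event = getattr(row, "event", True)
            try:
                records.append(
                    LifespanRecord(
                        animal_id=str(row.animal_id),
                        age_days=float(row.age_days),
                        genotype=str(row.genotype),
                        treatment=str(row.treatment),
                        sex=str(row.sex),
                        event=_coerce_event(raw_event),
                    )
                )
            except (CohortValidationError, ValueError, TypeError) as exc:
                raise CohortValidationError(f"row {idx}: {exc}") from exc
        return cls(tuple(records), protocol_label=protocol_label)

    def subset(
        self,
        genotype: str | None = None,
        treatment: str | None = None,
        sex: str | None = None,
    ) -> "Cohort":
        """Sub-cohort matching the given factor levels (None = no filter)."""
        keep = [
            r
            for r in self.records
            if (genotype is None or r.genotype == genotype)
            and (treatment is None or r.treatment == treatment)
            and (sex is None or r.sex == sex)
        ]
        if not keep:
            raise CohortValidationError(
                f"no records match genotype={genotype!r}, treatment={treatment!r}, "
                f"sex={sex!r}"
            )
        return Cohort(tuple(keep), protocol_label=self.protocol_label)

    def group_counts(self) -> dict[tuple[str, str, str], int]:
        counts: dict[tuple[str, str, str], int] = {}
        for rec in self.records:
            counts[rec.cell] = counts.get(rec.cell, 0) + 1
        return counts


def _coerce_event(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if float(value) in (0.0, 1.0):
            return bool(value)
        raise ValueError(f"event flag must be 0/1 or boolean, got {value!r}")
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("true", "1", "t", "yes"):
            return True
        if v in ("false", "0", "f", "no"):
            return False
    raise ValueError(f"cannot interpret event flag {value!r}")


def read_lifespan_table(path: str | Path, **csv_options) -> Cohort:
    """Read a lifespan CSV into a validated :class:`Cohort`.

    The header must name ``animal_id, age_days, genotype, treatment, sex``;
    an ``event`` column is optional (default: death observed). Row order is
    preserved. Raises :class:`SchemaError` for missing columns and
    :class:`CohortValidationError` (citing the offending row index) for bad
    values.
    """
    path = Path(path)
    csv_options.setdefault("float_precision", "round_trip")
    df = pd.read_csv(path, dtype={"animal_id": str}, **csv_options)
    return Cohort.from_dataframe(df, protocol_label=path.stem)


def write_lifespan_table(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as CSV such that :func:`read_lifespan_table` inverts
    it exactly (full float precision, UTF-8, comma-separated)."""
    df = cohort.to_dataframe()
    # shortest round-trip decimal form; pandas' own float formatting can
    # drop the last ulp
    df["age_days"] = [repr(float(v)) for v in df["age_days"]]
    df.to_csv(path, index=False)


def validate_cohort(cohort: Cohort) -> dict[tuple[str, str, str], int]:
    """Return per-(genotype, treatment, sex) cell counts.

    Construction of a :class:`Cohort` already enforces the record-level
    invariants; this is the summary entry point the CLI prints.
    """
    return cohort.group_counts()
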