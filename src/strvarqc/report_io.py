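"""Record model and CSV I/O for per-interpretation variance diagnostics.

Each record corresponds to one STRmix interpretation (one row of the
study-style summary table exported from an Interpretation Report): a sample
identifier, a dataset/challenge label, true and assumed numbers of
contributors, the per-contributor template amounts in RFU, and the three
average variance parameters (allele, reverse stutter, forward stutter).

The template amount of the highest-level contributor, Tc, is always derived
from the stored contributor templates, never stored, so the two can never
disagree. Replicate interpretations of the same amplification appear as
separate rows and are pooled downstream as independent points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Dataset",
    "VarianceType",
    "InterpretationRecord",
    "LogPoint",
    "RecordValidationError",
    "tc_of",
    "to_log_points",
    "read_records",
    "write_records",
    "CSV_COLUMNS",
]


class Dataset(str, Enum):
    """Challenge condition under which a mixture was amplified/interpreted."""

    UNCHALLENGED = "unchallenged"
    INHIBITED = "inhibited"
    NOC_UNDER = "noc_under"
    DEGRADED = "degraded"
    SATURATED = "saturated"
    CELL_LINE = "cell_line"
    OTHER = "other"


class VarianceType(str, Enum):
    """The three per-interpretation average variance parameters."""

    ALLELE = "allele"
    REVERSE_STUTTER = "reverse_stutter"
    FORWARD_STUTTER = "forward_stutter"


class RecordValidationError(ValueError):
    """A record (or CSV row) violates the data-model invariants."""


@dataclass(frozen=True)
class InterpretationRecord:
    """One STRmix interpretation's variance diagnostics.

    Parameters
    ----------
    sample_id
        Free-text identifier of the interpretation.
    dataset
        Challenge condition label.
    noc_true, noc_assumed
        True and assumed number of contributors. For ``noc_under`` records
        ``noc_assumed <= noc_true``; for every other dataset they are equal.
    contributor_templates
        Per-contributor "Template (rfu)" values, all positive. Tc is their
        maximum (see :func:`tc_of`).
    allele_var, rev_stutter_var, fwd_stutter_var
        Average variance parameters (c^2, unitless), all positive.
    """

    sample_id: str
    dataset: Dataset
    noc_true: int
    noc_assumed: int
    contributor_templates: tuple[float, ...]
    allele_var: float
    rev_stutter_var: float
    fwd_stutter_var: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "dataset", Dataset(self.dataset))
        object.__setattr__(
            self, "contributor_templates", tuple(float(t) for t in self.contributor_templates)
        )
        if not self.contributor_templates:
            raise RecordValidationError(
                f"record {self.sample_id!r}: contributor_templates must be non-empty"
            )
        if any(not (t > 0) or not math.isfinite(t) for t in self.contributor_templates):
            raise RecordValidationError(
                f"record {self.sample_id!r}: contributor templates must be finite and > 0"
            )
        for name in ("allele_var", "rev_stutter_var", "fwd_stutter_var"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise RecordValidationError(
                    f"record {self.sample_id!r}: {name} must be finite and > 0, got {v}"
                )
        if self.noc_true < 1 or self.noc_assumed < 1:
            raise RecordValidationError(
                f"record {self.sample_id!r}: contributor numbers must be positive"
            )
        if self.dataset is Dataset.NOC_UNDER:
            if self.noc_assumed > self.noc_true:
                raise RecordValidationError(
                    f"record {self.sample_id!r}: noc_assumed > noc_true for a "
                    "NOC-underestimate record"
                )
        elif self.noc_assumed != self.noc_true:
            raise RecordValidationError(
                f"record {self.sample_id!r}: noc_assumed must equal noc_true "
                f"outside the noc_under dataset"
            )

    def variance(self, parameter_type: VarianceType) -> float:
        """The average variance parameter of the given type."""
        return {
            VarianceType.ALLELE: self.allele_var,
            VarianceType.REVERSE_STUTTER: self.rev_stutter_var,
            VarianceType.FORWARD_STUTTER: self.fwd_stutter_var,
        }[VarianceType(parameter_type)]


@dataclass(frozen=True)
class LogPoint:
    """One point of a log10(variance parameter) vs log10(Tc) scatter."""

    x: float  # log10(Tc)
    y: float  # log10(variance parameter)
    parameter_type: VarianceType


def tc_of(record: InterpretationRecord) -> float:
    """Template (RFU) of the highest-level contributor: max of the templates."""
    if not record.contributor_templates:
        raise RecordValidationError("contributor_templates must be non-empty")
    return max(record.contributor_templates)


def to_log_points(
    records: Iterable[InterpretationRecord], parameter_type: VarianceType
) -> list[LogPoint]:
    """Map records to (log10(Tc), log10(variance)) points for one parameter."""
    parameter_type = VarianceType(parameter_type)
    points = []
    for rec in records:
        points.append(
            LogPoint(
                x=math.log10(tc_of(rec)),
                y=math.log10(rec.variance(parameter_type)),
                parameter_type=parameter_type,
            )
        )
    return points


# CSV dialect: RFC-4180, UTF-8, mandatory header; contributor templates are a
# semicolon-separated list within one cell.
CSV_COLUMNS = [
    "sample_id",
    "dataset",
    "noc_true",
    "noc_assumed",
    "contributor_templates",
    "allele_var",
    "rev_stutter_var",
    "fwd_stutter_var",
]

_TEMPLATE_SEP = ";"


def write_records(records: Sequence[InterpretationRecord], path: str | Path) -> None:
    """Write records to CSV (see :data:`CSV_COLUMNS` for the dialect)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "dataset": r.dataset.value,
            "noc_true": r.noc_true,
            "noc_assumed": r.noc_assumed,
            "contributor_templates": _TEMPLATE_SEP.join(repr(t) for t in r.contributor_templates),
            "allele_var": repr(r.allele_var),
            "rev_stutter_var": repr(r.rev_stutter_var),
            "fwd_stutter_var": repr(r.fwd_stutter_var),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path) -> list[InterpretationRecord]:
    """Read records from CSV, reporting every malformed row by line number."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordValidationError(f"{path}: missing columns {missing}")

    records: list[InterpretationRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            templates = tuple(
                float(t) for t in str(row["contributor_templates"]).split(_TEMPLATE_SEP) if t != ""
            )
            records.append(
                InterpretationRecord(
                    sample_id=str(row["sample_id"]),
                    dataset=Dataset(str(row["dataset"])),
                    noc_true=int(row["noc_true"]),
                    noc_assumed=int(row["noc_assumed"]),
                    contributor_templates=templates,
                    allele_var=float(row["allele_var"]),
                    rev_stutter_var=float(row["rev_stutter_var"]),
                    fwd_stutter_var=float(row["fwd_stutter_var"]),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise RecordValidationError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return records
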