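"""Benchmark flagging of interpretations and exceedance summaries.

Each interpretation's three variance parameters are compared, in log10
space, against four benchmark lines:

1. the fitted polynomial regression (the typical value at that Tc),
2. the empirical 99th-percentile band (regression + z residual SDs),
3. the prior gamma mode (constant in Tc), and
4. the prior gamma 99th percentile (constant in Tc).

A dataset tracking unchallenged expectations puts about half its points
above each "typical" line (1, 3) and ~1% above each "elevated" line (2, 4).

Flags use strict inequality (ties do not flag) and are advisory only: a
flagged interpretation is a prompt for closer scrutiny of the
electropherogram and genotype weights, never an automatic rejection.
Records whose Tc falls outside the calibration range are still classified
but marked ``extrapolated``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calibration import EmpiricalBand, predict
from .gamma_priors import PriorBenchmarks
from .report_io import Dataset, InterpretationRecord, VarianceType, tc_of

__all__ = [
    "Benchmark",
    "ParameterFlags",
    "FlagReport",
    "ExceedanceSummary",
    "flag_record",
    "flag_records",
    "flags_to_frame",
    "summarize_flags_table",
    "summarize_exceedance",
]

logger = logging.getLogger(__name__)


class Benchmark(str, Enum):
    REGRESSION = "regression"
    EMPIRICAL_99 = "empirical_99"
    PRIOR_MODE = "prior_mode"
    PRIOR_99 = "prior_99"


@dataclass(frozen=True)
class ParameterFlags:
    """Exceedance of the four benchmark lines for one variance parameter.

    ``exceeds_prior_mode`` is ``None`` when the prior mode is 0 (shape <= 1)
    and the mode line is disabled. Invariants: exceeding the empirical 99th
    band implies exceeding the regression; exceeding the prior 99th
    percentile implies exceeding the prior mode (when defined).
    """

    parameter_type: VarianceType
    exceeds_regression: bool
    exceeds_empirical_99: bool
    exceeds_prior_mode: Optional[bool]
    exceeds_prior_99: bool
    extrapolated: bool

    def exceeds(self, benchmark: Benchmark) -> Optional[bool]:
        return {
            Benchmark.REGRESSION: self.exceeds_regression,
            Benchmark.EMPIRICAL_99: self.exceeds_empirical_99,
            Benchmark.PRIOR_MODE: self.exceeds_prior_mode,
            Benchmark.PRIOR_99: self.exceeds_prior_99,
        }[Benchmark(benchmark)]


@dataclass(frozen=True)
class FlagReport:
    """All parameter flags for one interpretation record."""

    record: InterpretationRecord
    flags: Mapping[VarianceType, ParameterFlags]


def flag_record(
    record: InterpretationRecord,
    calibrations: Mapping[VarianceType, EmpiricalBand],
    priors: Mapping[VarianceType, PriorBenchmarks],
) -> FlagReport:
    """Classify one record's three variance parameters against all benchmarks.

    Comparisons are strict (y > line) in log10 space, so a borderline value
    sitting exactly on a line does not flag. The empirical lines depend on
    Tc: the same variance value can flag at one template level and not at
    another.
    """
    x = math.log10(tc_of(record))
    flags: dict[VarianceType, ParameterFlags] = {}
    for vt in VarianceType:
        if vt not in calibrations:
            raise KeyError(f"no calibration supplied for parameter type {vt.value!r}")
        if vt not in priors:
            raise KeyError(f"no prior benchmarks supplied for parameter type {vt.value!r}")
        band = calibrations[vt]
        prior = priors[vt]
        y = math.log10(record.variance(vt))
        mean = predict(band.model, x, warn_extrapolation=False)
        lo, hi = band.model.x_range
        flags[vt] = ParameterFlags(
            parameter_type=vt,
            exceeds_regression=y > mean,
            exceeds_empirical_99=y > mean + band.offset,
            exceeds_prior_mode=(y > prior.log10_mode) if prior.log10_mode is not None else None,
            exceeds_prior_99=y > prior.log10_q99,
            extrapolated=not (lo <= x <= hi),
        )
    return FlagReport(record=record, flags=flags)


def flag_records(
    records: Iterable[InterpretationRecord],
    calibrations: Mapping[VarianceType, EmpiricalBand],
    priors: Mapping[VarianceType, PriorBenchmarks],
) -> list[FlagReport]:
    """Flag every record; logs extrapolation and disabled-benchmark counts."""
    reports = [flag_record(r, calibrations, priors) for r in records]
    n_extrap = sum(1 for rep in reports if any(f.extrapolated for f in rep.flags.values()))
    disabled = [vt.value for vt, p in priors.items() if p.log10_mode is None]
    logger.info("flagged %d records (%d extrapolated)", len(reports), n_extrap)
    if disabled:
        logger.warning("prior mode line disabled for: %s", ", ".join(disabled))
    return reports


@dataclass(frozen=True)
class ExceedanceSummary:
    """Percentage of interpretations exceeding each benchmark, per dataset.

    ``percentages``: rows = (parameter, benchmark) MultiIndex, columns =
    dataset labels, values in [0, 100]. ``counts`` holds the per-cell
    denominators (records with the benchmark defined).
    """

    percentages: pd.DataFrame
    counts: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Formatted grid with percentages rounded to 2 decimals."""
        return self.percentages.round(2)


def flags_to_frame(flag_reports: Sequence[FlagReport]) -> pd.DataFrame:
    """Long-form table: one row per record x parameter with benchmark booleans.

    ``exceeds_prior_mode`` is empty where the mode line is disabled. This is
    the per-record flags CSV the CLI emits and re-reads.
    """
    rows = []
    for rep in flag_reports:
        for vt, f in rep.flags.items():
            rows.append(
                {
                    "sample_id": rep.record.sample_id,
                    "dataset": rep.record.dataset.value,
                    "parameter": vt.value,
                    "exceeds_regression": f.exceeds_regression,
                    "exceeds_empirical_99": f.exceeds_empirical_99,
                    "exceeds_prior_mode": f.exceeds_prior_mode,
                    "exceeds_prior_99": f.exceeds_prior_99,
                    "extrapolated": f.extrapolated,
                }
            )
    return pd.DataFrame(rows)


def summarize_flags_table(flags: pd.DataFrame) -> ExceedanceSummary:
    """Summarize a long-form flags table (as written by :func:`flags_to_frame`)."""
    rows = []
    for _, row in flags.iterrows():
        for bm in Benchmark:
            val = row[f"exceeds_{bm.value}"]
            if pd.isna(val) or val == "":
                continue
            if isinstance(val, str):  # CSV round-trip stores booleans as text
                val = val.strip().lower() == "true"
            rows.append((row["parameter"], bm.value, row["dataset"], bool(val)))
    return _summarize_long(pd.DataFrame(rows, columns=["parameter", "benchmark", "dataset", "exceeds"]))


def summarize_exceedance(flag_reports: Sequence[FlagReport]) -> ExceedanceSummary:
    """Tabulate exceedance percentages per dataset x parameter x benchmark."""
    if not flag_reports:
        raise ValueError("need at least one flag report to summarize")
    return summarize_flags_table(flags_to_frame(flag_reports))


def _summarize_long(long: pd.DataFrame) -> ExceedanceSummary:
    grouped = long.groupby(["parameter", "benchmark", "dataset"])["exceeds"]
    pct = (100.0 * grouped.mean()).unstack("dataset")
    n = grouped.count().unstack("dataset")
    order = pd.MultiIndex.from_product(
        [[vt.value for vt in VarianceType], [bm.value for bm in Benchmark]],
        names=["parameter", "benchmark"],
    )
    pct = pct.reindex([ix for ix in order if ix in pct.index])
    n = n.reindex(pct.index)
    return ExceedanceSummary(percentages=pct, counts=n)
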