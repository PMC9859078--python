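"""Synthetic interpretation-record generator.

Emulates the statistical structure the calibration assumes for a pooled set
of interpretation diagnostics: for each record, log10(Tc) is drawn
log-uniformly over the calibration span, and each of the three
log10(variance parameter) values follows a degree-4 polynomial trend in
log10(Tc) plus homoscedastic normal noise, plus a per-dataset additive
shift encoding how each challenge condition perturbs that parameter.

Defaults are the shipped reference trends and band-implied residual SDs; the
challenge shifts are calibrated so that, under the homoscedastic normal
model, each (dataset, parameter) cell shows roughly the empirical-99th-band
exceedance rate reported for the corresponding challenge study — the shift
is sigma * (2.326 + Phi^-1(rate)). Only the directions and ordering of
effects are structural targets; exact percentages in any one draw are
binomial noise around those rates.

What this generator does NOT emulate: the discrete template dilution ladders
of real validation designs, heteroscedasticity or Tc-dependent challenge
effects, cross-correlation among the three parameters within a record, and
detection-threshold censoring. Passing tests on this data demonstrate the
pipeline's statistical machinery, not kit-specific behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import DEFAULT_Z
from .report_io import Dataset, InterpretationRecord, VarianceType
from .reference import REFERENCE_BAND_OFFSETS, REFERENCE_COEFFICIENTS, REFERENCE_X_RANGE

__all__ = ["GeneratorSpec", "generate", "default_challenge_shifts", "default_residual_sds"]


def default_residual_sds() -> dict[VarianceType, float]:
    """Reference residual SDs in log10 units (band offset / 2.326)."""
    return {vt: off / DEFAULT_Z for vt, off in REFERENCE_BAND_OFFSETS.items()}


def default_challenge_shifts() -> dict[Dataset, dict[VarianceType, float]]:
    """Per-dataset additive log10 shifts of each variance parameter.

    Directions follow the challenge-study findings: inhibition pushes
    reverse stutter up while leaving allele and forward stutter nearly
    unchanged; NOC underestimation and cell-line mixtures push allele up
    most; degradation moderately elevates allele and reverse stutter;
    saturation elevates all three with reverse stutter largest. Magnitudes
    are the normal-tail inversions described in the module docstring.
    """
    A, R, F = VarianceType.ALLELE, VarianceType.REVERSE_STUTTER, VarianceType.FORWARD_STUTTER
    return {
        Dataset.UNCHALLENGED: {A: 0.0, R: 0.0, F: 0.0},
        Dataset.INHIBITED: {A: 0.046, R: 0.295, F: 0.104},
        Dataset.NOC_UNDER: {A: 0.162, R: 0.065, F: 0.042},
        Dataset.DEGRADED: {A: 0.141, R: 0.189, F: 0.089},
        Dataset.SATURATED: {A: 0.192, R: 0.375, F: 0.218},
        Dataset.CELL_LINE: {A: 0.144, R: 0.030, F: -0.019},
        Dataset.OTHER: {A: 0.0, R: 0.0, F: 0.0},
    }


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic dataset.

    ``dataset_counts`` maps each challenge label to the number of records to
    generate under it. Trend coefficients are ascending per parameter;
    ``residual_sds`` are the homoscedastic log10 noise SDs; ``tc_log10_bounds``
    bound the log-uniform Tc draw.
    """

    dataset_counts: Mapping[Dataset, int]
    seed: int
    trend_coefficients: Mapping[VarianceType, tuple[float, ...]] = field(
        default_factory=lambda: dict(REFERENCE_COEFFICIENTS)
    )
    residual_sds: Mapping[VarianceType, float] = field(default_factory=default_residual_sds)
    tc_log10_bounds: tuple[float, float] = REFERENCE_X_RANGE
    challenge_shifts: Mapping[Dataset, Mapping[VarianceType, float]] = field(
        default_factory=default_challenge_shifts
    )

    def __post_init__(self) -> None:
        lo, hi = self.tc_log10_bounds
        if not lo < hi:
            raise ValueError(f"tc_log10_bounds must be ordered, got {self.tc_log10_bounds}")
        for vt, sd in self.residual_sds.items():
            if sd < 0 or not np.isfinite(sd):
                raise ValueError(f"residual_sd for {VarianceType(vt).value} must be >= 0")
        for ds, shifts in self.challenge_shifts.items():
            for vt, s in shifts.items():
                if not np.isfinite(s):
                    raise ValueError(f"shift for ({ds}, {vt}) must be finite")
        for ds, n in self.dataset_counts.items():
            if n < 0:
                raise ValueError(f"dataset count for {ds} must be >= 0")


def _polyval(coeffs: tuple[float, ...], x: float) -> float:
    acc = 0.0
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


def generate(spec: GeneratorSpec) -> list[InterpretationRecord]:
    """Generate records per the spec; deterministic under its seed.

    Contributor templates are filled with Tc as the maximum plus smaller
    dummy contributors consistent with the drawn number of contributors.
    NOC-underestimate records report one contributor fewer than the truth.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.tc_log10_bounds
    records: list[InterpretationRecord] = []
    for dataset in sorted(spec.dataset_counts, key=lambda d: Dataset(d).value):
        dataset = Dataset(dataset)
        n = spec.dataset_counts[dataset]
        shifts = spec.challenge_shifts.get(dataset, {})
        for i in range(n):
            x = rng.uniform(lo, hi)
            tc = 10.0**x
            variances = {}
            for vt in VarianceType:
                y = (
                    _polyval(tuple(spec.trend_coefficients[vt]), x)
                    + float(shifts.get(vt, 0.0))
                    + rng.normal(0.0, spec.residual_sds[vt])
                )
                variances[vt] = 10.0**y
            if dataset is Dataset.NOC_UNDER:
                noc_true = int(rng.integers(2, 5))
                noc_assumed = noc_true - 1
            else:
                noc_true = int(rng.integers(1, 5))
                noc_assumed = noc_true
            minors = tc * rng.uniform(0.05, 0.9, size=noc_true - 1)
            records.append(
                InterpretationRecord(
                    sample_id=f"{dataset.value}-{i:05d}",
                    dataset=dataset,
                    noc_true=noc_true,
                    noc_assumed=noc_assumed,
                    contributor_templates=(tc, *minors),
                    allele_var=variances[VarianceType.ALLELE],
                    rev_stutter_var=variances[VarianceType.REVERSE_STUTTER],
                    fwd_stutter_var=variances[VarianceType.FORWARD_STUTTER],
                )
            )
    return records
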