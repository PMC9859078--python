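"""Shipped reference calibration and prior-gamma parameters.

These are the published GlobalFiler / STRmix v2.8 validation values from the
study this package operationalizes: degree-4 polynomial trends of
log10(variance parameter) on log10(Tc) fitted to ~3300 unchallenged
interpretations, the +2.326 SD band offsets, and the prior gamma
(shape, scale) pairs from the laboratory's Model Maker run. They let the
flagging pipeline run out of the box; laboratories calibrating their own kit
and settings should refit with ``strvarqc calibrate``.

Reference residual SDs are recovered as offset / 2.326 since only the
product (the band offset in log10 units) is published.
"""

from __future__ import annotations

from .calibration import DEFAULT_Z, CalibrationModel, EmpiricalBand
from .gamma_priors import GammaPrior, PriorBenchmarks, prior_bands
from .report_io import VarianceType

__all__ = [
    "REFERENCE_COEFFICIENTS",
    "REFERENCE_BAND_OFFSETS",
    "REFERENCE_X_RANGE",
    "DEFAULT_PRIORS",
    "reference_model",
    "reference_band",
    "reference_bands",
    "default_priors",
    "default_prior_benchmarks",
]

# Ascending coefficients (b0 ... b4) of the published log-log trends.
REFERENCE_COEFFICIENTS: dict[VarianceType, tuple[float, ...]] = {
    VarianceType.ALLELE: (5.5312, -8.2618, 4.8535, -1.2206, 0.1122),
    VarianceType.REVERSE_STUTTER: (-13.404, 23.456, -13.619, 3.3258, -0.2892),
    VarianceType.FORWARD_STUTTER: (-0.1678, 1.7016, -1.0891, 0.313, -0.0348),
}

# Published +2.326 SD band offsets, log10 units.
REFERENCE_BAND_OFFSETS: dict[VarianceType, float] = {
    VarianceType.ALLELE: 0.2156,
    VarianceType.REVERSE_STUTTER: 0.2755,
    VarianceType.FORWARD_STUTTER: 0.1779,
}

# log10(Tc) span of the calibration data (~32 RFU to ~16 kRFU).
REFERENCE_X_RANGE: tuple[float, float] = (1.5, 4.2)

# Prior gamma (shape, scale) per variance parameter. Scale parameterization:
# the published modes equal (alpha - 1) * beta.
DEFAULT_PRIORS: dict[VarianceType, GammaPrior] = {
    VarianceType.ALLELE: GammaPrior(VarianceType.ALLELE, alpha=3.891, beta=1.131),
    VarianceType.REVERSE_STUTTER: GammaPrior(VarianceType.REVERSE_STUTTER, alpha=1.557, beta=6.436),
    VarianceType.FORWARD_STUTTER: GammaPrior(VarianceType.FORWARD_STUTTER, alpha=1.526, beta=4.552),
}


def reference_model(parameter_type: VarianceType) -> CalibrationModel:
    """Reference trend for one parameter (no inference stats: raw data unavailable)."""
    vt = VarianceType(parameter_type)
    return CalibrationModel(
        parameter_type=vt,
        coefficients=REFERENCE_COEFFICIENTS[vt],
        residual_sd=REFERENCE_BAND_OFFSETS[vt] / DEFAULT_Z,
        x_range=REFERENCE_X_RANGE,
    )


def reference_band(parameter_type: VarianceType, z: float = DEFAULT_Z) -> EmpiricalBand:
    """Reference band (trend + z*SD upper limit) for one parameter."""
    return EmpiricalBand(model=reference_model(parameter_type), z=z)


def reference_bands(z: float = DEFAULT_Z) -> dict[VarianceType, EmpiricalBand]:
    """All three reference bands, keyed by variance type."""
    return {vt: reference_band(vt, z) for vt in VarianceType}


def default_priors() -> dict[VarianceType, GammaPrior]:
    return dict(DEFAULT_PRIORS)


def default_prior_benchmarks(p: float = 0.99) -> dict[VarianceType, PriorBenchmarks]:
    """Mode and p-quantile benchmark lines of the shipped priors."""
    return {vt: prior_bands(prior, p) for vt, prior in DEFAULT_PRIORS.items()}
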