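"""Prior gamma benchmarks for the variance parameters.

During validation, probabilistic-genotyping software builds a gamma prior for
each variance parameter from a training set of single-source profiles. The
mode of that prior, and a chosen upper quantile (the 99th percentile by
convention), serve as constant horizontal benchmark lines on the
log10(variance) vs log10(Tc) plane.

Parameterization
----------------
``beta`` is the **scale** parameter (mean = alpha*beta), NOT the rate. Gamma
parameterizations are a classic trap: the convention here is fixed by the
closed-form mode ``(alpha - 1) * beta`` for ``alpha > 1``, which matches the
shipped reference priors' printed modes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .report_io import VarianceType

__all__ = ["GammaPrior", "PriorBenchmarks", "gamma_mode", "gamma_quantile", "prior_bands"]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape=alpha, scale=beta) prior for one variance parameter."""

    parameter_type: VarianceType
    alpha: float  # shape, unitless
    beta: float  # scale, units of the variance parameter

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameter_type", VarianceType(self.parameter_type))
        if not (self.alpha > 0) or not (self.beta > 0):
            raise ValueError(
                f"gamma prior for {self.parameter_type.value}: alpha and beta must be > 0"
            )


@dataclass(frozen=True)
class PriorBenchmarks:
    """Mode and upper-quantile benchmarks of a prior, raw and in log10.

    ``log10_mode`` is ``None`` when the mode is 0 (shape <= 1), in which case
    flagging against the mode line is disabled.
    """

    parameter_type: VarianceType
    mode: float
    q99: float
    log10_mode: Optional[float]
    log10_q99: float


def gamma_mode(prior: GammaPrior) -> float:
    """Mode of the prior: (alpha - 1) * beta for alpha > 1, else 0."""
    if prior.alpha > 1.0:
        return (prior.alpha - 1.0) * prior.beta
    return 0.0


def gamma_quantile(prior: GammaPrior, p: float) -> float:
    """The p-quantile of Gamma(shape=alpha, scale=beta), 0 < p < 1.

    Computed by inverting the regularized incomplete gamma function; no
    sampling involved.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"quantile probability must be in (0, 1), got {p}")
    return float(stats.gamma.ppf(p, prior.alpha, scale=prior.beta))


def prior_bands(prior: GammaPrior, p: float = 0.99) -> PriorBenchmarks:
    """Constant-in-Tc benchmark lines derived from a prior.

    The solid line is the prior mode; the dotted line is the ``p``-quantile
    (99th percentile by default). Both are returned raw and as log10 values,
    ready to draw on the log-log diagnostic plane.
    """
    mode = gamma_mode(prior)
    q = gamma_quantile(prior, p)
    if mode > 0.0:
        log10_mode: Optional[float] = math.log10(mode)
    else:
        warnings.warn(
            f"{prior.parameter_type.value} prior has shape <= 1: mode is 0, "
            "mode-line flagging disabled",
            stacklevel=2,
        )
        log10_mode = None
    return PriorBenchmarks(
        parameter_type=prior.parameter_type,
        mode=mode,
        q99=q,
        log10_mode=log10_mode,
        log10_q99=math.log10(q),
    )
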