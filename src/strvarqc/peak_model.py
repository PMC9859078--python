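"""Lognormal peak-height variance model.

The continuous profile model treats the log10 ratio of observed to modeled
(expected) peak height as normal with mean 0 and variance equal to the
variance parameter divided by the relevant peak height:

    log10(observed / expected) ~ N(0, c2 / relevant_height)

so the spread grows with the variance parameter c2 and shrinks as peaks get
taller. For alleles the relevant height is the expected height of the peak
itself; for -1 repeat stutter it is conventionally the observed height of
the parent allele; other stutters use the expected stutter height.

This module simulates peak observations under that model and recovers the
variance parameter from observed/expected pairs by maximum likelihood. The
composite shifted-lognormal model for peaks carrying both allele and stutter
signal is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PeakObservation", "simulate_peaks", "estimate_variance_param"]


@dataclass(frozen=True)
class PeakObservation:
    """One observed/expected peak pair with its variance-scaling height (RFU)."""

    expected_height: float
    observed_height: float
    relevant_height: float

    def __post_init__(self) -> None:
        for name in ("expected_height", "observed_height", "relevant_height"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")


def simulate_peaks(
    variance_param: float,
    relevant_heights: Sequence[float],
    seed: int | np.random.Generator,
) -> list[PeakObservation]:
    """Draw peak observations with expected = relevant height.

    log10 ratios are drawn independently N(0, variance_param / height);
    deterministic under a fixed seed.
    """
    if not (variance_param > 0):
        raise ValueError(f"variance_param must be > 0, got {variance_param}")
    heights = np.asarray(relevant_heights, dtype=float)
    if heights.size == 0 or np.any(heights <= 0):
        raise ValueError("relevant_heights must be non-empty and all > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log_ratios = rng.normal(0.0, np.sqrt(variance_param / heights))
    return [
        PeakObservation(
            expected_height=float(h),
            observed_height=float(h * 10.0**lr),
            relevant_height=float(h),
        )
        for h, lr in zip(heights, log_ratios)
    ]


def estimate_variance_param(observations: Sequence[PeakObservation]) -> float:
    """MLE of the variance parameter from observed/expected pairs.

    Under the model each height-weighted squared log10 ratio is an unbiased
    draw of c2, so the MLE is their mean:
    (1/N) * sum h_i * log10(obs_i / exp_i)^2.
    """
    if len(observations) < 2:
        raise ValueError(f"need at least 2 observations, got {len(observations)}")
    terms = [
        o.relevant_height * np.log10(o.observed_height / o.expected_height) ** 2
        for o in observations
    ]
    return float(np.mean(terms))
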