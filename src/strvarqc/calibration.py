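"""Polynomial calibration of variance-parameter working ranges.

The calibration regresses log10(variance parameter) on log10(Tc) with an
ordinary-least-squares polynomial (degree 4 by default, matching the
curvature seen across the Tc range in validation data) and attaches the
standard OLS inference: R^2, overall F p-value, per-coefficient two-sided
99% confidence intervals and t p-values, plus a Jarque-Bera normality test
of the residuals.

The empirical upper working limit is the fitted mean plus ``z`` residual
standard deviations. With homoscedastic normal residuals, z = 2.326 puts the
line at the one-sided 99th percentile of the scatter around the trend. z is
kept at 2.326 exactly (the conventional rounded normal deviate) rather than
Phi^-1(0.99) = 2.32634..., so that shipped reference offsets reproduce
arithmetically; it is configurable.

All replicate interpretations are pooled as independent points (unweighted
OLS); no clustering correction is applied — a documented limitation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .gamma_priors import GammaPrior
from .report_io import LogPoint, VarianceType

__all__ = [
    "CalibrationModel",
    "EmpiricalBand",
    "fit_poly4",
    "fit_polynomial",
    "predict",
    "predict_upper",
    "empirical_band",
    "jarque_bera",
    "save_calibration",
    "load_calibration",
    "DEFAULT_Z",
]

DEFAULT_Z = 2.326

# Vandermonde condition number above which the fit warns about collinearity.
_CONDITION_WARN = 1e12


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted (or reference) polynomial trend in log-log space.

    ``coefficients`` are ascending: coefficients[k] multiplies x^k.
    ``residual_sd`` is the SD of the regression residuals in log10 units,
    computed with the unbiased n - (degree + 1) denominator. The inference
    fields are ``None`` for reference calibrations loaded from published
    coefficients, where the raw points are unavailable.
    """

    parameter_type: VarianceType
    coefficients: tuple[float, ...]
    residual_sd: float
    x_range: tuple[float, float]
    n: Optional[int] = None
    r_squared: Optional[float] = None
    f_pvalue: Optional[float] = None
    coef_ci99: Optional[tuple[tuple[float, float], ...]] = None
    coef_t_pvalues: Optional[tuple[float, ...]] = None
    jb_statistic: Optional[float] = None
    jb_pvalue: Optional[float] = None

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1


@dataclass(frozen=True)
class EmpiricalBand:
    """Upper working limit: fitted trend + z residual SDs (offset in log10)."""

    model: CalibrationModel
    z: float = DEFAULT_Z

    def __post_init__(self) -> None:
        if not (self.z > 0):
            raise ValueError(f"z must be > 0, got {self.z}")

    @property
    def offset(self) -> float:
        return self.z * self.model.residual_sd


def jarque_bera(residuals: Sequence[float]) -> tuple[float, float]:
    """Jarque-Bera normality test with moment-based skewness and kurtosis.

    JB = (n/6) * (S^2 + (K - 3)^2 / 4) with S = m3 / m2^(3/2) and
    K = m4 / m2^2 (central sample moments, no bias correction), referred to
    the upper tail of chi-square with 2 df. Requires n >= 3 and non-constant
    input (the moment estimators are defined whenever m2 > 0).
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError(f"Jarque-Bera needs at least 3 residuals, got {r.size}")
    r = r - r.mean()
    m2 = np.mean(r**2)
    if m2 <= 0.0:
        raise ValueError("Jarque-Bera undefined for zero-variance input")
    skew = np.mean(r**3) / m2**1.5
    kurt = np.mean(r**4) / m2**2
    jb = r.size / 6.0 * (skew**2 + 0.25 * (kurt - 3.0) ** 2)
    from scipy import stats

    return float(jb), float(stats.chi2.sf(jb, df=2))


def fit_polynomial(points: Sequence[LogPoint], degree: int = 4) -> CalibrationModel:
    """OLS fit of y on [1, x, ..., x^degree] with full inference.

    Needs at least degree + 3 points (>= 2 residual df) and at least
    degree + 1 distinct x values; fewer distinct x make the design
    rank-deficient and raise.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n_params = degree + 1
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    ptypes = {p.parameter_type for p in points}
    if len(ptypes) != 1:
        raise ValueError(f"points must share one parameter type, got {sorted(ptypes)}")
    parameter_type = ptypes.pop()
    if x.size < n_params + 2:
        raise ValueError(f"need at least {n_params + 2} points for a degree-{degree} fit")
    if np.unique(x).size < n_params:
        raise ValueError(
            f"need at least {n_params} distinct x values for a degree-{degree} fit; "
            f"got {np.unique(x).size}"
        )

    design = np.vander(x, n_params, increasing=True)
    cond = np.linalg.cond(design)
    if cond > _CONDITION_WARN:
        warnings.warn(
            f"ill-conditioned polynomial design (cond ~ {cond:.2e}); "
            "coefficients may be unstable",
            stacklevel=2,
        )
    res = sm.OLS(y, design).fit()

    resid = np.asarray(res.resid)
    residual_sd = float(np.sqrt(resid @ resid / (x.size - n_params)))

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-14 * max(1.0, float(y @ y)):
        warnings.warn("zero total variance in y; R^2 reported as 0", stacklevel=2)
        r_squared, f_pvalue = 0.0, float("nan")
    else:
        r_squared, f_pvalue = float(res.rsquared), float(res.f_pvalue)

    try:
        jb_stat, jb_p = jarque_bera(resid)
    except ValueError:  # perfect fit: residuals are numerically constant
        jb_stat, jb_p = float("nan"), float("nan")

    ci = res.conf_int(alpha=0.01)
    return CalibrationModel(
        parameter_type=parameter_type,
        coefficients=tuple(float(c) for c in res.params),
        residual_sd=residual_sd,
        x_range=(float(x.min()), float(x.max())),
        n=int(x.size),
        r_squared=r_squared,
        f_pvalue=f_pvalue,
        coef_ci99=tuple((float(lo), float(hi)) for lo, hi in ci),
        coef_t_pvalues=tuple(float(p) for p in res.pvalues),
        jb_statistic=jb_stat,
        jb_pvalue=jb_p,
    )


def fit_poly4(points: Sequence[LogPoint]) -> CalibrationModel:
    """Degree-4 fit, the default calibration model."""
    return fit_polynomial(points, degree=4)


def predict(model: CalibrationModel, x: float, *, warn_extrapolation: bool = True) -> float:
    """Fitted mean at x (Horner evaluation); warns outside the calibration range."""
    if not math.isfinite(x):
        raise ValueError(f"x must be finite, got {x}")
    lo, hi = model.x_range
    if warn_extrapolation and not (lo <= x <= hi):
        warnings.warn(
            f"log10(Tc) = {x:.4g} outside the {model.parameter_type.value} "
            f"calibration range [{lo:.4g}, {hi:.4g}]; extrapolating",
            stacklevel=2,
        )
    acc = 0.0
    for c in reversed(model.coefficients):
        acc = acc * x + c
    return acc


def predict_upper(band: EmpiricalBand, x: float, *, warn_extrapolation: bool = True) -> float:
    """Upper working limit at x: fitted mean + z * residual_sd."""
    return predict(band.model, x, warn_extrapolation=warn_extrapolation) + band.offset


def empirical_band(model: CalibrationModel, z: float = DEFAULT_Z) -> EmpiricalBand:
    """Attach the +z*SD upper band to a fitted model."""
    return EmpiricalBand(model=model, z=z)


# ---------------------------------------------------------------------------
# Calibration artifact: human-readable JSON so flagging can run without
# refitting. Holds per-parameter model + band z + the gamma priors.


def _model_to_dict(band: EmpiricalBand) -> dict:
    m = band.model
    return {
        "coefficients": list(m.coefficients),
        "residual_sd": m.residual_sd,
        "x_range": list(m.x_range),
        "n": m.n,
        "r_squared": m.r_squared,
        "f_pvalue": m.f_pvalue,
        "coef_ci99": [list(c) for c in m.coef_ci99] if m.coef_ci99 is not None else None,
        "coef_t_pvalues": list(m.coef_t_pvalues) if m.coef_t_pvalues is not None else None,
        "jb_statistic": m.jb_statistic,
        "jb_pvalue": m.jb_pvalue,
        "z": band.z,
    }


def save_calibration(
    bands: Mapping[VarianceType, EmpiricalBand],
    priors: Mapping[VarianceType, GammaPrior],
    path: str | Path,
) -> None:
    """Serialize per-parameter bands and priors to a JSON artifact."""
    payload = {
        "parameters": {
            VarianceType(vt).value: {
                **_model_to_dict(band),
                "prior": {
                    "alpha": priors[VarianceType(vt)].alpha,
                    "beta": priors[VarianceType(vt)].beta,
                },
            }
            for vt, band in bands.items()
        }
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(
    path: str | Path,
) -> tuple[dict[VarianceType, EmpiricalBand], dict[VarianceType, GammaPrior]]:
    """Load a calibration artifact written by :func:`save_calibration`."""
    payload = json.loads(Path(path).read_text())
    bands: dict[VarianceType, EmpiricalBand] = {}
    priors: dict[VarianceType, GammaPrior] = {}
    for name, entry in payload["parameters"].items():
        vt = VarianceType(name)
        model = CalibrationModel(
            parameter_type=vt,
            coefficients=tuple(entry["coefficients"]),
            residual_sd=entry["residual_sd"],
            x_range=tuple(entry["x_range"]),
            n=entry.get("n"),
            r_squared=entry.get("r_squared"),
            f_pvalue=entry.get("f_pvalue"),
            coef_ci99=(
                tuple((lo, hi) for lo, hi in entry["coef_ci99"])
                if entry.get("coef_ci99") is not None
                else None
            ),
            coef_t_pvalues=(
                tuple(entry["coef_t_pvalues"])
                if entry.get("coef_t_pvalues") is not None
                else None
            ),
            jb_statistic=entry.get("jb_statistic"),
            jb_pvalue=entry.get("jb_pvalue"),
        )
        bands[vt] = EmpiricalBand(model=model, z=entry.get("z", DEFAULT_Z))
        priors[vt] = GammaPrior(parameter_type=vt, alpha=entry["prior"]["alpha"], beta=entry["prior"]["beta"])
    return bands, priors
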