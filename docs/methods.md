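# Methods

## Model and procedure

The package operationalizes a secondary-diagnostic QC procedure for
continuous probabilistic genotyping. The underlying peak model treats the
log10 ratio of observed to modeled peak height as zero-mean normal with
variance `c² / h`, where `c²` is a per-run average variance parameter
(allele, reverse stutter, or forward stutter) and `h` the relevant peak
height in RFU — the expected height of the peak itself for alleles, the
observed parent-allele height for −1 stutter, and the expected stutter
height otherwise. The composite shifted-lognormal model for peaks that carry
both allele and stutter signal is out of scope and not implemented.

The QC procedure itself works at the level of the per-interpretation
averages. With `x = log10(Tc)` (Tc = template of the highest-level
contributor — using only the top contributor avoids over-weighting mixtures
with many contributors) and `y = log10(c²)`, the calibration step fits

    y = b0 + b1 x + b2 x² + b3 x³ + b4 x⁴ + ε,  ε ~ N(0, σ²)

by unweighted OLS on pooled unchallenged interpretations, one parameter type
at a time. Degree 4 is the default because the diagnostic trends are
distinctly non-linear over the usable Tc range (stutter detection switches
on around Tc ≈ 617 RFU for reverse and ≈ 1000 RFU for forward stutter,
producing inflections); the API accepts other degrees. The empirical upper
working limit is the fit plus `z·σ` with `z = 2.326`, the one-sided normal
99th-percentile deviate. `z` is deliberately the conventional rounded value
rather than `Φ⁻¹(0.99) = 2.32634…` so that shipped reference offsets
reproduce arithmetically; it is configurable everywhere it appears.

Two further benchmarks come from the validation-time gamma prior
`Gamma(shape α, scale β)` of each variance parameter: its mode `(α−1)β`
(0 when α ≤ 1, in which case the mode line is disabled with a warning) and
its 99th percentile, computed by inverting the regularized incomplete gamma
function. β is the **scale** parameter; the scale convention is pinned down
by the closed-form mode matching the shipped reference priors' printed
modes, and is worth stating loudly because gamma rate/scale confusion is a
classic defect.

Flagging compares `y` against all four lines with **strict** inequality —
a value exactly on a line does not flag, a conservative tie rule. The two
regression-derived lines depend on Tc, so an identical variance value can
flag for a low-Tc interpretation and not for a high-Tc one; this is the
central improvement over constant prior-based yardsticks. Records whose Tc
falls outside the calibration range are still classified but marked
`extrapolated` (casework cannot refuse out-of-range Tc; the warning channel
is the flag, not an exception). Flags never reject a record: they are
advisory prompts for scrutiny.

## Inference and numerical choices

- OLS via a numerically stable solver on the Vandermonde design; the fit
  refuses designs with fewer than degree+1 distinct x values and warns when
  the condition number exceeds 1e12.
- `σ` uses the unbiased `n − (degree+1)` denominator. At calibration-scale
  n (thousands) the distinction from `1/n` is negligible, but it is fixed
  and documented here.
- Per-coefficient two-sided 99% confidence intervals and t p-values use
  Student-t OLS inference; the overall F test and R² are reported as fitted.
  The intervals are per-coefficient, not simultaneous.
- Residual normality is screened with the Jarque-Bera test in its classic
  moment-estimator form, `JB = (n/6)(S² + (K−3)²/4)` against χ²(2); the
  asymptotic p-value is used (no small-sample Monte Carlo). Minimum n is 3
  (the moment estimators exist whenever the residual variance is positive),
  though p-values are only meaningful at realistic calibration sizes.
- Zero-total-variance responses (constant y) yield R² = 0 with a warning
  rather than NaN; perfect fits yield NaN Jarque-Bera fields.
- Gamma quantiles have relative accuracy ~1e-10 (verified by round-trip
  against an independent CDF away from the saturated tails).
- The variance-parameter MLE from observed/expected peak pairs is
  `(1/N) Σ hᵢ·(log10 Oᵢ/Eᵢ)²`; each term is `c²·χ²₁`, so the estimator is
  unbiased with relative RMSE `√(2/N)`. No detection-threshold censoring is
  applied.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `degree` | 4 | — | captures the stutter-detection inflections |
| `z` | 2.326 | log10 SDs | one-sided 99th percentile band |
| `p_prior` | 0.99 | probability | prior-gamma upper benchmark quantile |
| priors (α, β) | reference values | β in c² units | laboratory Model Maker output; override per kit |
| `tc_log10_bounds` | (1.5, 4.2) | log10 RFU | calibration span, ~32 RFU to ~16 kRFU |

All are surfaced in the YAML pipeline config; nothing is hard-coded.

## Synthetic data generator

The generator emulates exactly the structure the calibration assumes: per
record, `log10(Tc)` uniform over the calibration span; per parameter,
`y = poly(x) + shift(dataset, parameter) + N(0, σ²)` with the reference
trend coefficients and band-implied σ as defaults; variance `= 10^y`;
contributor templates filled with Tc as the maximum plus smaller dummies
consistent with the drawn number of contributors. Everything is
deterministic under the spec seed.

The per-dataset challenge shifts were fixed once, before any testing, by
inverting the one-sided normal tail against the empirical-99th-band
exceedance rate each challenge condition shows in validation data:
`shift = σ·(2.326 + Φ⁻¹(rate))`, rounded to 3 decimals. That encodes the
qualitative pattern — inhibition elevates reverse stutter (+0.295) while
barely moving allele (+0.046); contributor-number underestimation (+0.162)
and cell-line mixtures (+0.144) elevate allele most; degradation moderately
elevates allele and reverse stutter; saturation elevates all three with
reverse stutter largest (+0.375). Exact exceedance percentages in any one
draw are binomial noise around those rates and are not a generator target.

What the generator does **not** emulate: discrete dilution-ladder Tc
designs, heteroscedastic or Tc-dependent challenge effects,
cross-correlation of the three parameters within a run, detection-threshold
censoring, or MCMC run-to-run dependence between replicate interpretations
of one amplification. Consequently, green tests demonstrate the statistical
machinery (fit, bands, flags, summaries) on data satisfying the model's
assumptions; they do not validate any particular kit or laboratory's
variance behavior, for which a laboratory must calibrate on its own
unchallenged data.

## Design choices where the design was open

- Pooling replicate interpretations as independent points matches how the
  reference calibration was produced, but understates uncertainty when
  replicates cluster; a clustering correction is future work.
- Calibration artifacts are human-readable JSON so flagging can run without
  refitting; round-trip identity is tested.
- Percentages in summaries are reported to 2 decimals; booleans in the
  flags CSV round-trip as text.
- The pipeline calibrates on records labelled `unchallenged` (configurable)
  and flags all records, mirroring how challenged datasets are assessed
  against unchallenged expectations.
- "Template (rfu)" averages are treated as opaque positive reals; no
  assumption is made about which posterior summary they are.

## Problem sizes

The test suite and acceptance script use: 2000 unchallenged + 400 per
challenged dataset for end-to-end exceedance (large enough that the ~1%
tail target has a tight binomial interval), 200 seeded replicates at
n = 500 for CI coverage and residual-SD recovery, N = 5000 peak
observations for variance-MLE recovery, and n ≤ 50 instances for
normal-equations equivalence. The whole suite runs in a few seconds.

## Known limitations

- Upper working limits only; the software's own default lower bound
  (0.5 × prior mode) makes a lower band redundant here.
- No likelihood-ratio or genotype-weight computation: exceedance flags say
  "more variance than usual was needed", nothing more.
- The reference calibration is kit- and protocol-specific; shipping it is a
  convenience, not a substitute for local calibration.
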