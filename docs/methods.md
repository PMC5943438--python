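# Methods

## Scientific setting

Field carcinogenesis alters chromatin packing at length scales well below
the diffraction limit throughout an organ, before and around any visible
lesion. Partial-wave spectroscopic (PWS) microscopy detects this through
the *disorder strength*

    L_d = sigma2_n * l_c

the variance of refractive-index fluctuations times their correlation
length. PWS acquires a backscattered image at each wavelength from 500 to
700 nm (7 nm steps, 29 bands), giving an image cube (x, y, lambda) with
one interference spectrum per pixel; the fluctuations of that spectrum
carry L_d. This package implements the full analysis chain that links
rectal-colonocyte L_d measurements to 5-year colorectal-cancer (CRC)
risk: a forward optical model, the L_d estimator, a synthetic patient
cohort calibrated to the published group summary statistics, the
group-comparison statistics, a cumulative-risk meta-model, and the
exponential risk-vs-L_d fit.

## Forward optical model (`pwsfield.forward`)

The intracellular refractive index is modelled as a 1-D axial profile
n0 + dn(z): a stationary zero-mean Gaussian process with variance
`sigma2_n` and exponential autocorrelation exp(-|dz|/l_c), sampled as the
discretized Ornstein–Uhlenbeck AR(1) recursion with rho = exp(-dz/l_c).
The reflectance is single-scattering (Born) with a scalar field
interfering against the Fresnel reflection r0 of the cell's top surface:

    R(lambda) = | r0 + c * sum_z dn(z) exp(i 2 k n0 lambda z) dz |^2

Defaults: n0 = 1.38, ambient index 1.0 (dry, ethanol-fixed smears),
thickness 2000 nm, dz = 1 nm, coupling c = 0.002 /nm. The coupling is
deliberately perturbative: the fluctuation is then dominated by the cross
term, linear in dn, and the spectral-fluctuation variance is proportional
to sigma2_n. At larger couplings the mean-intensity normalization makes
the statistic visibly sublinear in sigma2_n (we measured ~15% distortion
at c = 0.01 over the default parameter grid), which is an instrument
regime, not an analysis regime.

**Validity regime.** For an exponential-correlation medium the power
spectral density at the backscattering spatial frequency q = 2 k n0 is
S(q) ∝ sigma2_n * l_c / (1 + q^2 l_c^2). The estimator is therefore
proportional to sigma2_n * l_c only while q*l_c ≲ 1, i.e.
l_c ≲ lambda/(4 pi n0) ≈ 30 nm at these wavelengths, and *decreases*
again beyond ~33 nm. All calibration and monotonicity tests run inside
this regime (l_c ≤ 30 nm); chromatin correlation lengths of interest are
of this order. Pixels are statistically independent — the analysis only
ever averages over regions of interest, so lateral correlation is
irrelevant to any tested claim. No detector noise is simulated.

## L_d estimation (`pwsfield.ld`)

Per pixel: divide the spectrum by its mean (intensity invariance),
remove a degree-1 polynomial in wavenumber (the reflectance baseline;
at 29 spectral samples a higher order would start absorbing genuine
interference oscillations), and take the variance of the residual.
A single scalar calibration maps that variance to L_d; it is fitted
through the origin on ≥3 simulated reference cubes with known
sigma2_n * l_c. Closure: across a 3×3 (sigma2_n, l_c) grid with
sigma2_n ∈ {1e-4, 3e-4, 9e-4} and l_c ∈ {5, 8, 12} nm the calibrated
estimate recovers ground truth within ±15% (the residual spread is the
S(q) roll-off across the l_c grid plus Monte-Carlo error). Cells are
supplied as ROI masks (labelled image or boolean masks); patient mean
L_d averages cell means, with SE = SD/sqrt(n_cells).

The cohort QC statistic is the average intrapatient SE divided by the
interpatient SD of patient means, in percent; at 40 cells/patient and
the default within-patient noise it sits near 1.6%, below the 2% bound
the measurement design is meant to guarantee.

## Synthetic cohort (`pwsfield.cohort`)

190 patients in six groups crossing current status (control vs adenoma
≥5 mm) with colonic history (none / low-risk NDA / high-risk AA-or-CRC).
Group sizes follow the published decomposition: 95 / 10 (6 AA-history +
4 CRC-history) / 36 (13 NDA + 23 AA current) / 19 (3 NDA + 16 AA
current). Only the sum of the two low-risk groups (30) is derivable; the
default split is control 10 / adenoma 20, the adenoma-20 split NDA 10 /
AA 10, and 3 CRC-history patients inside aa_high — all config-exposed.

Group L_d means are *calibrated*, not invented: each published
(effect size d, percent difference p) pair inverts in closed form to

    mean_b = mean_a (2 + p/100) / (2 − p/100),
    pooled_sd = (mean_a − mean_b) / d

(`invert_group_moments`). Anchoring control/no-history at 1 and chaining
through the comparison table gives control_high = 1.4570,
adenoma_no = 1.1906, adenoma_high = 1.7896 (the two independent routes to
it agree to 1e-4), with pooled SDs 0.528–0.653 as the per-group
interpatient SDs (per-group SDs are not separately recoverable — hence
the published Welch p-values are reported but cannot be matched exactly).
Two quantities are genuinely open and were fixed once: control_low
(midpoint of its neighbours, 1.2285, preserving the published monotone
trend) and the NDA/AA subtype decomposition (aa_no = 1.25; the remaining
subtype means then solve the weighted-average and AA-contrast
constraints). Demographics (age mean±SD, %male, smoking, alcohol) are
drawn per group from the published demographic table; ages are rounded
and floored at 18. Per-cell noise SD defaults to 0.06 (normalized).

What the generator does *not* emulate: per-patient adenoma counts,
non-normal or skewed L_d distributions, correlations between
demographics and L_d within a group, and the particular realized
ordering of the real study's group means. Passing tests therefore
validate the analysis machinery and its calibration, not any clinical
claim about new cohorts.

## Risk meta-model (`pwsfield.risk`)

    group risk = [ AA_r * Σ_i AA2CRC_i + N_c * (1 − e^(−CRC_m · horizon)) ]
                 / (N_a + N_c)

with AA_r the group's probability of a future advanced adenoma over the
~3.4-year surveillance interval, AA2CRC_i = 1 − exp(−annual_rate(age_i,
sex_i) × 1.6 y) the per-patient progression probability over the
remaining 1.6 years of the 5-year horizon, and CRC_m = 0.35%/yr the
metachronous-cancer rate applied to the N_c CRC-history patients (who
contribute *only* that term — the group equation is implemented exactly
as displayed, with no adenoma-recurrence term for them, and AA_r enters
multiplicatively, not through the exponential form).

The per-group AA_r values and the age/sex progression table of the
source meta-analysis are not public. The shipped defaults are documented
placeholders: the annual AA→CRC rate rises linearly from 2%/yr at age 50
to 6%/yr at age 80 (clamped, 5-year bands, male ×1.3); AA_r grows
roughly geometrically across the risk ordering (0.030 for
control/no-history to 0.198 for current-AA/high-risk-history), monotone
along both the history and current-status axes with current status the
stronger predictor, as surveillance-colonoscopy data show. The model
structure — not these constants — is the implemented contribution;
substitute real tables via `RiskConfig`.

## Exponential correlation fit (`pwsfield.expfit`)

Risk is modelled as an exponential function of group mean L_d and fitted
by OLS on ln(risk) — deterministic and closed-form, with R² on the log
scale and F = R²(n−2)/(1−R²) on (1, n−2) df. That identity reproduces
the published (R² = 0.946, F = 104) pair at n = 8 groups, which is also
the evidence that the original R² was computed on the log-linear scale.
Eight groups enter the fit (current adenomas split into NDA/AA; the
3-patient NDA/high-history cell is excluded).

The headline published R² is not desk-reproducible — it was computed on
unpublished per-patient data. The pipeline therefore reports two fits:
the default uses the *calibrated group centres* as x (these are the
study's observed group means, recovered from the comparison table), and
reaches r² ≈ 0.93 with the default risk tables; the second uses the
freshly simulated cohort's observed group means, which add interpatient
sampling noise (SE up to ~0.2 for the n = 10 groups) on top — under the
calibrated SDs that fit's r² has median ≈ 0.73 across seeds, which is a
property of resampling noise, not of the calibration, and is reported
but not asserted.

## Numerical choices and degenerate inputs

* Moment inversion rejects |percent difference| ≥ 200 (undefined ratio),
  zero effect size (infinite SD), zero percent difference (degenerate
  zero SD), and sign-inconsistent (d, p) pairs (negative implied SD).
* Simulated L_d values are floored at 1e-6 (physical length scale).
* Cohen's d uses (n−1)-weighted sample variances in the pooled SD.
  Sign conventions: for an ordered pair, d = (first − second)/pooled SD
  and %diff = 100·(second − first)/mean-of-means, so the published
  positive-%diff/negative-d pairing is reproduced.
* ANCOVA tests covariates one at a time (age numeric; sex, alcohol
  2-level factors; smoking 3-level), OLS with type-II sums of squares;
  collinear designs raise with a diagnostic.
* `cumulative_risk` uses expm1 for small-rate accuracy; ages outside the
  progression table clamp to the nearest band with a logged warning.
* Welch t with both variances zero: p = 1 for identical means, error
  otherwise. Constant-y exponential fits return slope 0, r² 0, F 0.
* Test problem sizes (cube grids of 16–32 pixels per side, 10^6-draw
  round trips, 1000-replicate ANCOVA null) were chosen as the smallest
  sizes at which Monte-Carlo error is comfortably inside each asserted
  tolerance.

## Known limitations

* The Born forward model saturates for l_c ≳ 30 nm; absolute L_d values
  (nm units) are not comparable to published tissue values, and only
  relative/normalized L_d is used downstream.
* Risk-table defaults are placeholders (above); per-group absolute risks
  should not be quoted against the literature without substituting the
  real tables.
* Welch p-values of the comparison table depend on per-group SDs that
  are not recoverable; they are computed on the synthetic cohort but not
  calibrated.
* No multiple-testing correction is applied (none was in the original
  analysis) and no survival modelling is attempted; risk is a
  closed-form meta-model, not simulated events.
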