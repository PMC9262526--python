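# Methods

## The adaptive test

**Response model.** Items follow Samejima's graded response model with
between-item multidimensionality: each item measures exactly one of the six
syndrome elements. For an item with discrimination *a* > 0 and strictly
increasing thresholds *b₁ < … < b_{K−1}*, the cumulative probability of
responding in category ≥ k is logistic(a(θ_e − b_k)); category probabilities
are successive differences. This is the minimal item-response model
consistent with per-element ordered symptom ratings; within-item
multidimensionality, exposure control and content balancing are out of
scope.

**Selection.** The next item maximizes the determinant of the accumulated
posterior information matrix, A = prior precision + Σ administered item
informations, plus the candidate's information (D-optimality). Under
between-item dimensionality each candidate is a rank-one update on its
element's diagonal, so det(A + i·e_e e_eᵀ) = det(A)·(1 + i·(A⁻¹)_ee); the
implementation ranks candidates by i·(A⁻¹)_ee, which is exactly the
determinant ordering, and the test suite checks equality with brute-force
determinant search on small banks. Ties break to the lowest item id for
reproducibility.

**Estimation.** Severities are estimated by maximum a posteriori under a
configurable multivariate-normal prior (default: independent standard
normal per element). Newton–Raphson starts at the prior mean with
step-halving on log-posterior decreases; the GRM log-likelihood is concave,
so the full Newton step almost always suffices. Convergence is declared at
gradient 2-norm < 1e-8 (at most 100 iterations; non-convergence is flagged
and the best iterate returned). The posterior SE is sqrt(diag(inverse
negative Hessian)) at the mode, which reduces to the prior SD with no items
answered.

**Termination and reporting.** Sessions stop after exactly 20 answers (the
deployed system's rule). Element scores are reported as 50 + 10·θ̂, a
T-score convention chosen so typical scores land in the 35–55 range the
application reports; the deployed system's true θ→score map is not public.

**Synthetic bank.** Because the deployed 215-item bank's calibrated
parameters are proprietary, banks are simulated: 215 items allocated
round-robin across elements (35–36 each), log-normal discriminations
(meanlog 0.2, sdlog 0.3, median ≈ 1.22 — typical of well-calibrated symptom
items), and per-element-centred ordered thresholds from N(center, 1) with a
0.05 minimum gap. Whether the deployed system selects from the full bank or
a 39-item extract is ambiguous in the source description; selection here
runs over the full bank by default, and a smaller bank can be passed
anywhere one is accepted.

## Standardization

Per element, standardized = (raw − min)/(max − min)×100 with min/max fitted
on the pooled baseline + follow-up calibration scores, so both timepoints
share one scale (the source states only "full-sample"; pooling is this
package's reading, and fitting on baseline alone is possible by passing only
baseline scores). Later out-of-range scores are clamped to [0, 100] with a
logged warning rather than rejected. Report rounding is 4 decimals, half
away from zero.

## Diagnostic evaluation

A positive model call is standardized score ≥ threshold (higher severity
score ⇒ syndrome present; the inequality direction is this package's
convention). The ROC is evaluated at every unique score plus an
all-negative sentinel; AUC is the trapezoidal area, equal to the
Mann–Whitney pair statistic with half-credit for ties. The diagnostic
threshold maximizes Youden's J = sensitivity + specificity − 1, ties going
to the lower (more sensitive) cut. Kappa bands follow the printed clinical
convention (≥ 0.75 excellent, 0.40–0.75 fair to good, < 0.40 poor, boundary
inclusive). McNemar's test uses the continuity-corrected χ² when the
discordant count b + c ≥ 25 and the exact two-sided binomial otherwise; the
switch point follows common biostatistical practice since the source names
only a "paired chi-square test".

## MCID estimation

Differences are follow-up − baseline on a higher-is-better instrument.
The anchor-based estimator pools all patients reporting change (any nonzero
anchor) by default; `improvers_only` and `somewhat_better` strata are
available because the source does not state which stratum fed its estimate.
Worseners' differences are sign-flipped so magnitudes do not cancel.
Normality ("normal or skewed distribution") is operationalized as
Shapiro–Wilk at α = 0.05: mean if normal, median otherwise; a zero median —
uninformative, as happens when most changed patients move little — falls
back to the mean with a `fallback_mean` flag, and a user-supplied expert
value can override it (the original expert-opinion substitution is not
reconstructible). The distribution-based estimator is ES × baseline SD
(n−1), ES = 0.2 by default with 0.5 retained for sensitivity analysis. The
weighted MCID is the exact arithmetic mean of the two, rounded only in
report output. Responsiveness uses the same normality gate to choose the
paired t-test or the Wilcoxon signed-rank test (zeros dropped; normal
approximation with tie correction beyond 25 nonzero pairs; an all-zero
difference vector is reported as p = 1 with a degenerate flag).

## Outcome linkage

Responders satisfy d ≥ MCID (boundary inclusive). Predictors are the six
continuous standardized score changes, oriented baseline − follow-up so
positive means improvement (scores fall with treatment); a `binary` coding
(change dichotomized at per-element cutoffs) is provided because the source
does not state its coding and some published coefficient magnitudes hint at
a binary predictor. Fits are unpenalized maximum likelihood via IRLS
(score max-norm < 1e-8), SEs from the inverse observed information, Wald =
(B/SE)² on 1 df. Quasi-separation (any |B| > 15) is flagged, never
penalized, mirroring the apparent unpenalized original fits. No multiplicity
correction is applied across the 9 × 6 grid (none was applied originally);
a Benjamini–Hochberg adjustment is available as supplementary output only.

## Synthetic cohort: what it does and does not emulate

The generator draws six latent severities from a multivariate normal with
configurable equicorrelation (default 0.3 — the source is silent on
inter-element dependence, and moderate positive correlation is typical of
co-occurring syndrome features). Follow-up severity is baseline minus a
per-element treatment effect plus N(0, 0.3²) visit noise; the default
effects (0.424, 0.041, 0.095, 0.042, 0.054, 0.186 logits for liver,
stomach, heat, spleen-dampness, qi deficiency, qi stagnation) reproduce the
reported pattern that liver and qi stagnation improve most and stomach and
spleen-dampness least. Clinician labels are truth (θ above a per-element
prevalence cutoff, default 0) flipped independently with probability 0.05.
QoL domain changes are loading-weighted severity improvements plus N(0, 5²)
noise on a 0–100 scale; baselines are N(60, 15²) with a mild (−2/logit)
severity gradient, and all values are clamped to [0, 100] after noise (the
clamp is logged). The total score is the mean of the eight domains — the
real instrument's aggregation rule is unpublished, and this choice is
isolated in one function. The 5-level anchor is deterministic given the
noiseless latent global change (cut thresholds; optional misreport
probability, default 0); default cuts sit at normal quantiles of the latent
change distribution chosen so the expected anchor mix matches the reported
follow-up distribution (3 worse / 93 unchanged / 156 somewhat better / 39
obviously better of 291), and `anchor_target_calibration` re-places them for
any target mix. Dropouts (default 9 of 300) are uniform at random — no
mechanism was reported.

Not emulated: real symptom semantics, item content, informative dropout,
floor/ceiling psychometrics of the real instrument, and the study's actual
baseline QoL dispersion (unreported; the default SD of 15 makes
distribution-based MCIDs land in a plausible 2–4-point range, not a
reproduction of the published ones). A green test therefore establishes
that the pipeline's statistics behave correctly on data with the assumed
structure — not that the published patient-level numbers (Youden thresholds
39/44/52/41/47/43, κ = 0.628, the regression coefficients) are recovered;
those depend on the unavailable clinical data.

## Numerical conventions

- All randomness flows from one master seed through named substreams
  (CRC-32 of the stage name mixed into the seed sequence), so stages can be
  re-run in isolation and full runs are byte-identical under a fixed seed.
- CSV round trips use `%.17g` formatting and round-trip float parsing, so
  write → read is exact.
- Ties: item selection and Youden thresholds break low; responder and
  diagnosis boundaries are inclusive (≥).
- Report rounding: 4 decimals half-away-from-zero for MCID tables,
  3 decimals for logistic tables with P printed as `<0.001` below 0.0005.

## Known limitations

- The MAP estimator's posterior SE uses the observed information; for very
  short tests it understates uncertainty relative to a fully Bayesian
  posterior.
- The D-optimal rule is greedy (one step ahead), as in deployed CAT systems.
- With 20 items over six dimensions (~3 items per element), per-element
  recovery is coarse (mean absolute error ≈ 0.4 logits); the diagnostic AUC
  criterion absorbs this, but individual θ̂ values should not be
  over-interpreted.
- The logistic linkage is associational; no causal interpretation is made.
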