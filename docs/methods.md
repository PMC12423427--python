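# Methods

## Coupling statistic

ROI-wise structure–function coupling is the Spearman rank correlation
between one region's structural connectivity profile and its functional
connectivity profile over selected edges. Choices that the statistic's
definition leaves open, and how this package resolves them:

- **Edge selection.** The default policy `sc_nonzero` keeps edges with
  structural weight > 0 only. Functional z values are continuous and almost
  never exactly zero, so conditioning on "both nonzero" would make the edge
  set depend on floating-point accidents; `both_nonzero` is nevertheless
  available as a configuration for data with hard-zeroed FC.
- **Directionality.** Probabilistic tractography is seed-based, so the SC
  matrix is directed. By default the profile of ROI *i* is its outgoing row
  wᵢⱼ, matching the seed-region framing; `sc_mode="symmetric"` uses
  (wᵢⱼ + wⱼᵢ)/2 instead. Both are supported because published practice
  varies and results can differ slightly.
- **Ties and degeneracy.** Ties get midranks. A correlation over fewer than
  `min_edges = 3` selected edges, or over a constant vector, is undefined
  and propagates as NaN — never as zero. Network coupling averages the
  defined member ROIs only; a network with no defined member yields NaN
  with a warning.

Within-network structural connectivity averages the directed weights over
ordered off-diagonal pairs (equivalent to averaging the symmetrized
matrix); within-network functional connectivity averages Fisher-z values
over unordered pairs, since FC is symmetric.

## Functional connectivity and QC

FC is atanh(r) elementwise on the Pearson correlation matrix of
preprocessed ROI time series. |r| is clamped at 1 − 10⁻⁷ before the
transform so that perfectly coupled synthetic series produce a large finite
z rather than an infinity. Band-pass filtering, nuisance regression and
smoothing are assumed done upstream; the package starts from clean series
or precomputed matrices.

The motion exclusion rule fails a subject iff mean framewise displacement
> 0.5 mm or any of the six rigid-body parameters > 3 mm/degrees, with
strict inequalities (a subject at exactly the threshold is retained). The
six parameters are interpreted as per-parameter maxima of absolute values
over frames; applying the rule to frame-to-frame deltas instead is a
plausible alternative reading that upstream pipelines sometimes use.

## Statistical battery

- **Group comparisons:** pooled-variance two-sample t for continuous
  variables; chi-square with Yates continuity correction for 2×2 tables.
  The continuity correction is the default because it reproduces standard
  clinical-software output for moderate cell counts; it can be switched off.
- **Standardized β:** every reported coefficient is b·SD(x)/SD(y) computed
  on the model's complete cases, applied uniformly to binary predictors as
  well — the convention of mainstream statistics packages. Missing data are
  handled complete-case per model with n reported; no imputation.
- **FDR:** Benjamini–Hochberg step-up, one family per stratum per analysis
  table (e.g., the 7 networks of one predictor within the mild stratum form
  one family). Family membership for multi-test batteries is configurable;
  per-table is the default.
- **Repeated-measures ANOVA:** classical within-subject decomposition with
  the Greenhouse–Geisser ε (from the double-centered condition covariance)
  applied to both degrees of freedom, so df₁ = ε(k−1) and df₂ = ε(k−1)(N−1).
  Huynh–Feldt is not offered; GG is the conservative standard and matches
  the df conventions this analysis reports. A condition sum of squares
  below 10⁻¹² of the total is treated as exactly zero so that identical
  conditions give F = 0 instead of a ratio of rounding noise. Post hoc
  all-pairs comparisons use t = (x̄ᵢ − x̄ⱼ)/√(2·MSₑ/N) on the pooled
  within-subject error with Tukey HSD p-values from the studentized-range
  distribution. The implementation is cross-checked in the test suite
  against pingouin's independent rm-ANOVA.
- **Severity rule:** severe iff periventricular Fazekas = 3 or deep
  Fazekas ≥ 2; both scores zero violates the cohort's inclusion criterion
  and raises an error rather than silently classifying.
- **Education** is treated as continuous years when used as a covariate.

## Prognosis

Follow-up scores are split at the quartiles (linear-interpolation
definition, inclusive: lower group ≤ Q1, upper group ≥ Q3, boundary ties
joining the extreme group; middle half excluded). The ROC uses the
midrank Mann–Whitney AUC, whose direction is *not* forced above 0.5 — the
hypothesis fixes the orientation (higher coupling → upper quartile). The
95% CI is DeLong's asymptotic interval by default, with a seeded bootstrap
(2,000 resamples) by flag. The operating cutoff maximizes the Youden index
among points whose sensitivity meets a floor (default 0.90); this
sensitivity-prioritized rule suits screening for decline risk, where missed
positives are costlier than false alarms. Ties in the masked Youden index
resolve toward the higher (more specific) cutoff.

## Synthetic cohort generator

The generator is the package's test surface and defines its study
conditions; its defaults are fixed, not tuning knobs:

- **Cohort:** 617 subjects; age 61 ± 7; 46.5% female; education ≈ 9 ± 3.5
  years; risk-factor prevalences 72.9/22.2/42.8/37.6/44.1% (hypertension,
  diabetes, hypercholesterolemia, smoking, drinking), hypertension tilted
  toward higher lesion burden.
- **WMH burden:** a latent standard normal (correlation 0.35 with age)
  maps to volume exp(0.48 + 1.30·z) mL — mean ≈ 3.8, SD ≈ 8 — and, through
  jittered thresholds, to periventricular and deep Fazekas scores. The
  thresholds (0.445 on the jittered latent for PWMH = 3 and DWMH ≥ 2) were
  calibrated once so the severity rule marks ≈ 39% of subjects severe;
  severity labels are rule-consistent by construction. Subjects whose two
  scores would both be zero are bumped to deep score 1, mirroring the
  inclusion criterion.
- **Effects:** within the mild stratum, log-volume drives the target
  network's (FPN) coupling with standardized β = 0.136; FPN coupling drives
  baseline digit span forward with β = 0.110; and, in the ~20% follow-up
  subset, follow-up digit span with β = 0.245 given baseline
  autocorrelation 0.6 (an assumed value — the within-subject correlation of
  repeated cognitive testing is not identified by any input here). The
  severe stratum instead carries a direct negative volume → cognition
  effect (−0.20) and no coupling effect. Residual variances are set from
  the sample systematic variance to make outcomes unit-variance, so the
  generating coefficients are standardized βs; configurations implying
  R² > 0.95 are rejected as infeasible.
- **Connectomes:** SC edges are kept with probability 1 − sparsity
  (default 0.6) with log-normal weights, symmetric by default (the
  directed per-row construction is available; its row normalization leaves
  the pooled log-weight distribution very slightly left-skewed, so the
  log-normal shape check targets the default construction). FC mixes the
  normal scores of the SC ranks with independent noise using weight
  w = 2·sin(πκ/6), which makes the *population Spearman correlation equal
  κ itself* in the Gaussian limit: the coupling knob is calibrated on the
  same scale as the estimand. κ = 1 yields exactly ρ = 1 (FC is a strictly
  monotone function of SC); κ = 0 yields expected ρ = 0. Per-network κ
  defaults follow the unimodal-to-transmodal gradient (SMN highest 0.35,
  FPN lowest 0.15). Optional time series use an exact factor construction
  (whitened Gaussian factors times the Cholesky of the eigen-clipped target
  correlation matrix), so `fc_from_timeseries(ts)` reproduces the returned
  FC to machine precision; this requires T ≥ n_roi + 2.
- **Table/connectome link.** When connectomes are requested, each subject's
  per-network κ is set to that subject's coupling column, so measured
  coupling tracks the generated value up to estimation noise. The
  statistical battery's effect sizes live at the table level; measured
  coupling from small synthetic connectomes is a noisy estimate of the
  generated target, which is why effect-recovery checks run on the
  table-level coupling.

What the generator does **not** emulate: spatial lesion geometry and
tract-specific disconnection, distance-dependent tractography biases,
hemodynamic/vascular confounds in BOLD, site or scanner effects, floor and
ceiling effects of cognitive tests, and informative follow-up dropout
(follow-up is a uniform random subset). Passing tests therefore validate
the estimators and their calibration under the assumed generative model,
not robustness to these real-data features.

## Analysis defaults

WMH volume enters regressions log-transformed by default: the volume
distribution is strongly right-skewed (log-normal in the generator, and
empirically so in clinical cohorts), and the generative effects act on the
log scale. `wmh_transform="raw"` switches to untransformed milliliters for
comparability with analyses that regress on raw volume.

Problem sizes used by the test suite and acceptance script — 42–63 ROI
parcellations for connectome-level checks, 100–200 replicates for recovery
and 500–1,000 for null calibration — were chosen to keep the full suite in
the minutes range on a single CPU while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- The ROI-wise statistic is Spearman correlation; harmonic
  (graph-spectral) and model-based coupling variants are out of scope.
- DeLong's CI is asymptotic; at very small class sizes the bootstrap flag
  is preferable.
- The cutoff-selection rule (Youden subject to a sensitivity floor) is one
  documented convention; other software may pick a different operating
  point on the same curve.
- `linear_assoc` codes only binary categoricals automatically;
  multi-level factors must be dummy-coded by the caller.
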