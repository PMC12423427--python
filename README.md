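# sfcoupling

Structure–function connectome coupling analysis for white matter
hyperintensity (WMH) cohorts.

WMH — hyperintense subcortical lesions on T2-FLAIR MRI and a hallmark of
cerebral small vessel disease — damages white matter tracts, yet cognition in
mildly affected patients is often preserved. One candidate mechanism is
adaptive remodeling of the correspondence between a brain region's
structural wiring and its functional interactions. This package implements
that analysis for researchers working with tractography-derived structural
connectomes and resting-state functional connectomes: it quantifies
region-wise structure–function coupling, aggregates it over the canonical
7-network cortical parcellation (400 parcels by default), stratifies
subjects by WMH severity, runs the covariate-adjusted association battery,
and evaluates baseline coupling as a prognostic marker of follow-up
cognitive performance.

## The statistic

For region *i* with structural profile **s**ᵢ = (wᵢⱼ)ⱼ≠ᵢ (tractography
connection probabilities) and functional profile **z**ᵢ = (zᵢⱼ)ⱼ≠ᵢ (Fisher
z-transformed Pearson correlations of BOLD time series), the ROI-wise
coupling is the Spearman rank correlation

ρᵢ = Spearman( {wᵢⱼ : wᵢⱼ > 0}, {zᵢⱼ : wᵢⱼ > 0} ),

computed over the edges with nonzero structural weight (midrank tie
handling; undefined below 3 edges). Network coupling is the mean of the
defined ρᵢ over the member regions of each of the seven networks (FPN, DAN,
DMN, LMN, SMN, VAN, VIN). Downstream, the package provides:

- WMH severity stratification: *severe* iff periventricular Fazekas = 3 or
  deep Fazekas ≥ 2, otherwise *mild*;
- pooled-variance t and Yates-corrected chi-square group comparisons;
- standardized-β OLS (β\* = b·SD(x)/SD(y)) with the analysis-specific
  covariate sets (age, sex, education, WMH volume, vascular risk factors,
  follow-up duration, baseline score), Benjamini–Hochberg FDR per stratum;
- one-way repeated-measures ANOVA across networks with Greenhouse–Geisser
  correction and Tukey-style post hoc paired comparisons;
- quartile-discrimination ROC (Mann–Whitney AUC, DeLong 95% CI, cutoff
  chosen by maximal Youden index subject to a sensitivity floor);
- a synthetic cohort generator producing connectomes and cohort tables with
  known standardized effects, so every stage can be verified end to end.

## Worked example

```python
from sfcoupling import SimulationConfig, run_pipeline
from sfcoupling.synthetic_cohort import gen_cohort, coupling_long

cfg = SimulationConfig(seed=42)          # 617 subjects, default conditions
cohort, _ = gen_cohort(cfg)
bundle = run_pipeline(cohort, coupling_long(cohort))

w = bundle["wmhv_coupling"]
print(w[w.stratum == "mild"][["outcome", "beta_std", "p_raw", "p_fdr", "n"]].round(3))
```

prints the mild-stratum association of (log) WMH volume with each network's
coupling:

```
outcome  beta_std  p_raw  p_fdr   n
net_DAN     0.008  0.878  0.924 378
net_DMN     0.023  0.665  0.924 378
net_FPN     0.150  0.004  0.028 378
net_LMN    -0.073  0.162  0.568 378
net_SMN    -0.005  0.924  0.924 378
net_VAN     0.022  0.672  0.924 378
net_VIN    -0.046  0.379  0.884 378
```

Only the frontoparietal network survives FDR: its generated effect
(standardized β = 0.136) is recovered at 0.150 in this replicate while the
six null networks stay flat. The same bundle carries the across-network
ANOVA and the prognosis ROC:

```
rm-ANOVA: F(5.92, 3647) = 1199.4, eps = 0.987, p = 0
ROC: AUC = 0.839 (95% CI 0.718-0.960), cutoff = 0.126, sens = 0.905, spec = 0.571
```

The equivalent shell workflow:

```bash
couple simulate --seed 42 --out-dir sim/
couple run --cohort sim/cohort.csv --coupling sim/coupling.csv --out-dir results/
couple roc --cohort sim/cohort.csv --coupling sim/coupling.csv --network FPN
```

## Layout

- `src/sfcoupling/parcellation_io.py` — parcellation scheme, connectome and
  result file I/O
- `src/sfcoupling/connectome.py` — Fisher-z FC, SC normalization,
  within-network summaries, motion QC
- `src/sfcoupling/coupling.py` — ROI-wise and network coupling
- `src/sfcoupling/cohort_stats.py` — severity rule and the statistical battery
- `src/sfcoupling/prognosis.py` — longitudinal models, quartile ROC
- `src/sfcoupling/synthetic_cohort.py` — the generator
- `src/sfcoupling/pipeline.py`, `cli.py` — orchestration and the `couple` CLI

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
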