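# sonopattern

Latent sonographic phenotyping of categorical breast-ultrasound features,
and the association of the resulting patterns with pathological non-response
to neoadjuvant chemotherapy (NAC).

## The problem

Most breast cancer patients respond to NAC; the clinically urgent group is
the small minority (~4%) with substantial residual disease at surgery
(residual cancer burden class III or Miller–Payne grade 1–2). Single
conventional-ultrasound descriptors predict this poorly, but clinicians read
sonograms as *patterns* — constellations of shape, margin, posterior-echo
and vascularity findings. `sonopattern` operationalizes that idea for a
cohort of N = 509 patients described by 23 categorical ultrasound features:

1. **Feature screening** by multiple correspondence analysis (MCA): a
   variable is kept when its categories contribute > 2% of the inertia of at
   least one of the first five dimensions.
2. **Latent class analysis (LCA)**: the finite mixture
   `P(y_i) = Σ_c π_c Π_j ρ_jc(y_ij)`, fitted by multi-start EM, with class
   enumeration by AIC / BIC / sample-size-adjusted BIC
   (`aBIC = −2LL + p·ln((N+2)/24)`), relative entropy, an approximate
   Lo–Mendell–Rubin adjusted likelihood-ratio test, and a parametric
   bootstrap likelihood-ratio test (BLRT).
3. **Distance-based comparators**: K-modes and Gower-distance hierarchical
   clustering with average silhouettes, entered into one audited selection
   rule together with the LCA candidates and the external validity
   (chi-square of cluster membership vs non-response).
4. **Firth bias-reduced logistic regression** of non-response on pattern
   membership plus clinical covariates — penalized likelihood
   `l*(β) = l(β) + ½ ln det I(β)`, finite under separation — with Wald
   odds-ratio inference and VIF collinearity checks.
5. **Rare-event-preserving bootstrap** (non-responders held fixed in every
   replicate, responders resampled to their original count) and
   outcome-stratified 10-fold cross-validation.
6. **Model-standardized subgroup risk differences** (high-risk vs
   non-high-risk profiles × chemotherapy regimen) with percentile CIs, and a
   **sensitivity rerun** excluding Miller–Payne-assessed cases.

Because the underlying patient data are not public, the package ships a
first-class synthetic-cohort generator whose defaults emulate the study
conditions (two patterns at 50.5%/49.5%, anchored class profiles such as
irregular shape 100% / lateral shadowing 76% vs 7%, a 4.32% marginal
non-response rate at a pattern odds ratio of 2.5, and 48 MP-assessed cases
carrying exactly 2 events).

## Worked example

```python
import sonopattern as sp
from sonopattern.pipeline import PipelineConfig, run_pipeline

cohort = sp.generate_cohort(sp.paper_emulation_config(), seed=1, exact_n_events=22)
report = run_pipeline(cohort, PipelineConfig(seed=11, fast=True))
print(report["selection"]["selected"])
print(report["patterns"]["counts"])
print([r for r in report["firth"]["or_table"] if r["term"] == "pattern_b"][0])
```

prints (seed 11, fast configuration):

```
lca/k=2
{'A': 270, 'B': 239}
{'term': 'pattern_b', 'beta': 0.830..., 'se': 0.443..., 'or': 2.294...,
 'ci_low': 0.964..., 'ci_high': 5.462..., 'p': 0.061...}
```

meaning: the audited selection picked the two-class latent model (the
K-modes and hierarchical candidates fail the silhouette floor, higher class
counts fail the enumeration tests), split the 509 patients 270/239 into
patterns A/B, and estimated that pattern-B membership carries about 2.3
times the odds of non-response — the sampling spread of this estimate over
seeds brackets the generating odds ratio of 2.5. The scripts in `examples/`
walk through each stage (simulation, class enumeration, clustering
comparison, rare-event regression, resampling validation, subgroup risk
differences, full pipeline + sensitivity rerun) and print a line on what
each number means; a CLI (`sonopattern simulate|run|sensitivity`) wraps the
same calls for shell use.

## Layout

- `src/sonopattern/` — `synthetic` (generator), `cohort` (I/O + QC),
  `mca`, `lca`, `clusters`, `selection`, `firth`, `resampling`, `riskdiff`,
  `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — model details, defaults, numerical choices, limitations
- `tests/` — unit, property and acceptance suites
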