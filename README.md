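# ihcrisk

Dual-chromogen immunostain quantification and nested case-control risk
modelling for benign prostate biopsy cohorts.

## The problem

Men whose prostate biopsy comes back benign remain at risk of a later
prostate-cancer diagnosis. Two inflammation-related proteins measurable
in that benign tissue — the transcription factor NF-κB and the cytokine
GDF-15 — plausibly shape early carcinogenesis in opposite directions.
Linking their expression to subsequent cancer requires an unusual
pipeline that spans image analysis and epidemiology:

1. **Stain quantification.** Slides are dual-stained (DAB brown for
   GDF-15, Ferangi Blue for NF-κB, hematoxylin counterstain). Each
   pixel's RGB value is converted to optical density
   (OD<sub>c</sub> = −log₁₀(I<sub>c</sub>/255)), tissue is separated
   from blank at mean-channel OD > 0.08, and the two chromogens are
   unmixed by colour deconvolution. A tissue pixel is marker-positive
   when its deconvolved stain OD exceeds 0.15. Each marker is summarised
   as PPEA (positive pixels / tissue pixels) and AEI (mean OD of
   positive pixels); the subject-level score is ln(PPEA × AEI).
2. **Study design.** Within a retrospective benign-biopsy cohort, each
   man diagnosed ≥ 1 year after entry becomes a case; a control is
   drawn by incidence-density sampling (with replacement) from everyone
   still cancer-free at the case's follow-up time, matched on race and
   ±2-year calipers on age and entry date.
3. **Inference.** 1:1 matched pairs are analysed by conditional
   logistic regression, which for pairs reduces exactly to an
   intercept-free logistic likelihood on within-pair covariate
   differences d = x_case − x_control:
   ℓ(β) = Σᵢ −ln(1 + e^(−βᵀdᵢ)). The package fits continuous, quartile
   (race-specific control-based cutpoints), linear-trend, stratified,
   and polynomial models, with Wald odds-ratio intervals and
   likelihood-ratio tests of nested fits — e.g. the quadratic risk model
   β₀ + PSA·β₁ + inflammation·β₂ + NF-κB·β₃ + GDF-15·β₄ + GDF-15²·β₅.

Because no patient data are public, the package ships a synthetic layer
with known ground truth at both ends: Beer–Lambert stain phantoms for
the imaging stage, and a simulated two-race cohort whose cancer hazard
depends log-linearly on NF-κB and quadratically on GDF-15 expression.

## Worked example

```python
from ihcrisk import SimParams, StudyConfig, run_full_analysis

cfg = StudyConfig(sim_params=SimParams(seed=1), match_seed=2)
res = run_full_analysis(cfg)
print(len(res.pairs), "pairs")
adj = res.models["adjusted"]
print(adj[["model", "term", "or", "p"]].head(5))
print("marker correlation r = %.3f" % res.correlation[0])
```

prints

```
718 pairs
             model        term        or         p
0  nfkb_continuous        nfkb  0.897137  0.005550
1    nfkb_quartile     nfkb_q2  0.815683  0.156391
2    nfkb_quartile     nfkb_q3  0.736587  0.047609
3    nfkb_quartile     nfkb_q4  0.580321  0.001218
4       nfkb_trend  nfkb_trend  0.841298  0.001208
marker correlation r = 0.461
```

Read: from a simulated 10,478-man cohort, 718 matched pairs were
formed. The adjusted continuous NF-κB odds ratio of 0.90 per unit of
ln(PPEA × AEI) recovers the simulation's protective hazard ratio of
0.85; the top-quartile OR of 0.58 and the significant downward trend
(OR 0.84 per quartile) show the same association on the categorical
scale. The cross-marker correlation pools both races; within race it is
0.39 by construction.

The same pipeline runs from the shell: `ihcrisk phantom`,
`ihcrisk quantify`, and `ihcrisk run-study --config study.yaml --out dir/`.

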