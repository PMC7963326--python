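# cryptmosaic

Mosaic OXPHOS-deficiency calling and stem-cell proliferation inference for
colonic crypts.

Aged colonic epithelium — and the PolgA mtDNA-mutator mouse that models it —
shows a *mosaic* of crypts in which mitochondrial respiratory-chain complexes
have dropped out: some crypts lose complex I (detected as low NDUFB8), some
complex IV (low MTCO1), some both, while mitochondrial mass (TOMM20, VDAC1)
stays normal. The question this package addresses is whether those deficient
crypts proliferate differently, measured by dual thymidine-analogue labelling
(CldU over four days, IdU in the final 15 h) of whole crypts and of their
LGR5-high stem cells.

`cryptmosaic` reimplements that analysis chain as a tested, seedable pipeline
over tabular per-crypt data, with a synthetic-data generator standing in for
the imaging measurements so every stage can be validated against known ground
truth. It is aimed at biostatisticians and quantitative biologists who want
the statistical machinery — deficiency calling, protocol simulation,
mixed-model inference — without any microscopy dependencies.

## The statistics at the core

**Deficiency calling.** Each crypt's mean marker intensity is normalized to
the mitochondrial mass marker and standardized against the pooled wild-type
cohort:

    z = (marker/mass − μ̂₊/₊) / σ̂₊/₊

A crypt is called deficient in a complex when z < −4.5 (strict); the four-way
category (NORMAL, CI_DEF, CIV_DEF, CI_CIV_DEF) is the combination of the two
calls. The raw mass markers are z-scored the same way purely as QC.

**Labelling simulation.** Each cell is an alternating-renewal process:
active runs of lognormal ~24 h cycles (S phase occupying a third of each
cycle), separated by exponential quiescent gaps. A cell acquires an analogue
when an S phase overlaps an availability window after an injection; Ki-67
marks cells mid-cycle at sacrifice. The key parameter is a division-rate
multiplier that acts through the quiescent gap so that a crypt's long-run
division rate — and hence its expected label counts — scales exactly
multiplicatively, which is the structure the downstream model assumes.

**Inference.** Counts are modelled with Poisson (label counts) or NB2
(cells per crypt) generalized linear mixed models with a per-mouse random
intercept:

    y_ij | u_i ~ Poisson(μ_ij),   log μ_ij = x_ijᵀβ + log(exposure) + u_i,
    u_i ~ N(0, σ_u²)

The marginal likelihood integrates u out by adaptive Gauss–Hermite
quadrature (nodes centred at each mouse's conditional mode, found by damped
Newton iteration); a dense trapezoid grid serves as an independent
brute-force oracle in the tests. Effects are reported as Wald rate ratios
exp(β̂ ± 1.96·se) with raw two-sided p-values.

## Worked example

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_classify_oxphos.py
```

The classifier, given only intensities, recovers the generator's mosaic
exactly at these effect sizes (output from the run above):

```
called vs generating truth (%):
                     true_pct  called_pct
genotype
+/+      NORMAL        100.00      100.00
+/mut    NORMAL         48.75       48.75
         CI_DEF         33.88       33.88
         CI_CIV_DEF     12.38       12.38
         CIV_DEF         5.00        5.00
mut/mut  CI_DEF         51.75       51.88
         CI_CIV_DEF     48.25       48.00
         CIV_DEF         0.00        0.12
```

Deficient crypts sit ~6 reference SDs below the wild-type cloud, so the
z < −4.5 rule separates the mixture almost perfectly; the 0.12% of
homozygote crypts called CIV-only are combined-deficient crypts whose
complex-I z-score landed just above the line. `03_simulate_labelling.py`,
`04_fit_glmms.py` and `05_effect_recovery.py` continue the chain: simulate
label counts for the classified crypts, fit the intra-mouse GLMM contrasts
(CI-deficient crypts show rate ratios ≈ 1.2 for analogue incorporation,
isolated CIV deficiency a decrease, cells-per-crypt no change), and verify
on replicate cohorts that a known 20% division-rate increase is recovered
without bias:

```
50 replicate cohorts, true division-rate increase 20%:
  mean recovered increase : 19.73% (Monte-Carlo SE 1.34)
  95% Wald CI coverage    : 0.920
```

The same stages are scriptable via the `cryptmosaic` CLI
(`simulate-intensities`, `classify`, `simulate-labelling`, `fit-glmm`,
`run-full`), all seeded and deterministic.

## Layout

- `src/cryptmosaic/` — library: `synthetic_cohort`, `oxphos_classifier`,
  `labelling`, `glmm`, `studies`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — unit, property and acceptance tests
- `docs/methods.md` — model assumptions, parameter choices, limitations
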