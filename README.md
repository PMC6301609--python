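# coastmix

Bayesian stable isotope mixing models (SIMMs) for reconstructing the marine
vs. terrestrial composition of individual diets from bone-collagen δ¹³C and
δ¹⁵N — aimed at archaeologists and isotope ecologists working in coastal
settings where marine foods are ¹³C- and ¹⁵N-enriched relative to C₃
terrestrial foods.

The package covers the full quantitative workflow around such a
reconstruction:

- **Data model & I/O** — validated CSV tables of food-source samples,
  consumer bone-collagen records, and a yearly atmospheric CO₂ δ¹³C series.
- **Corrections** — Suess-effect adjustment of modern δ¹³C back to a
  pre-industrial basis (terrestrial: −6.48‰ − δ¹³C_CO₂(year), added to the
  sample; marine: ×0.65), and additive tissue offsets (e.g. keratin →
  collagen-equivalent).
- **Group statistics** — K-nearest-neighbour randomization (KNNr) tests of
  group separation, Wilcoxon rank-sum / Kruskal–Wallis with Holm correction,
  a generalized (multivariate) Shapiro–Wilk normality test, and OLS of δ¹⁵N
  on δ¹³C with confidence bands.
- **Mixing polygons** — minimum convex polygons (convex hulls) in isotope
  space with boundary-inclusive point-in-polygon tests, used to screen
  trophic enrichment factor (TEF) choices: a consumer outside the source
  polygon cannot be any mixture of those sources.
- **The mixing model** — for diet proportions **p** on the K-simplex with a
  Dirichlet(α) prior, each isotope is modelled as

      wₖ = pₖcₖ / Σⱼ pⱼcⱼ                 (concentration dependence)
      μ  = Σₖ wₖ (μₖ + ε)                 (source mean + trophic enrichment)
      σ² = Σₖ wₖ² (σₖ² + σ_ε²)            (process error, no residual term)
      δ  ~ Normal(μ, σ²)

  sampled by adaptive random-walk Metropolis on the additive log-ratio
  transform of the simplex, with multiple seeded chains.
- **Diagnostics** — Gelman–Rubin R̂ and Geweke z-scores, with an escalating
  run-length protocol (re-fit with longer chains until R̂ < 1.05 for all
  proportions and ≤ 5% of variables per chain have |z| > 1.96), posterior
  correlation checks for indistinguishable sources (r < −0.7), and
  a-posteriori aggregation of draws into marine / terrestrial fractions.
- **Synthetic data** — a generator with known diet proportions and a
  simulate-and-refit harness measuring credible-interval coverage and the
  bias induced by mis-specified enrichment factors.

## Worked example

Fit one synthetic consumer whose true diet is known, with convergence
escalation and marine/terrestrial aggregation (`examples/03_fit_one_consumer.py`):

```text
consumer SYN001: d13C=-14.7, d15N=16.4
converged=True at escalation level 0; max Rhat=1.004
  terrestrial_plant        CI95 = [0.01, 0.39]
  terrestrial_vertebrate   CI95 = [0.02, 0.63]
  marine_invertebrate      CI95 = [0.04, 0.65]
  marine_vertebrate        CI95 = [0.01, 0.39]
marine: mean 0.52, CI95 [0.32, 0.71]
terrestrial: mean 0.48, CI95 [0.29, 0.68]
true marine fraction: 0.46
warning: terrestrial_plant and terrestrial_vertebrate indistinguishable (posterior r = -0.82)
```

The per-source intervals are wide — individual foods trade off against
isotopically similar neighbours, and the correlation check flags exactly
those pairs — but the aggregated marine fraction is well constrained and
covers the generating truth (0.46). That separation between what the data
can and cannot resolve is the central output of the method.

`examples/04_recovery.py` runs the calibration experiment:

```text
correct TEF:  CI95 coverage = 0.95, bias = +0.003, mean CI95 width = 0.34
eps13C +2:    CI95 coverage = 0.60, bias = -0.135  (marine fraction pushed toward terrestrial)
```

With the enrichment factor matching the generative value, 95% intervals
cover the truth at the nominal rate; shifting ε¹³C by +2‰ biases the marine
fraction down by ~0.14 — the quantitative footprint of choosing the wrong
TEF.

There is also a thin CLI (`coastmix pipeline config.yaml`,
`coastmix simulate`, `coastmix recover`) over the same library functions;
see `coastmix --help`.

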