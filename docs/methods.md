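# Methods

## The model

Each consumer is modelled independently. Diet is a proportion vector **p** on
the K-simplex (K = 4 food groups by default) with a Dirichlet(α) prior,
α = (1, 1, 1, 1) unless configured otherwise. For each isotope (carbon and
nitrogen, treated as independent given **p**), the consumer's bone-collagen
delta is normal with concentration-dependent mixture moments:

- weights `w_k = p_k c_k / Σ_j p_j c_j`, where `c_k` is the group's mean %C
  (or %N) by mass — a diet heavy in carbon-rich but nitrogen-poor plants
  contributes more to the carbon signal than to the nitrogen signal;
- mean `μ = Σ_k w_k (μ_k + ε)`, where `μ_k` is the group's mean delta and ε
  the trophic enrichment factor (TEF, collagen − diet) for that element;
- variance `σ² = Σ_k w_k² (σ_k² + σ_ε²)` — *process error only*: variability
  propagated from source spread and TEF uncertainty, with no residual term.
  This is the appropriate error structure for single-individual fits, where
  a residual term is not estimable.

TEF uncertainty enters analytically (σ_ε² added to each source variance)
rather than as a sampled latent variable; under the normal process model the
marginal likelihood is identical and the sampler is cheaper. Source group
means and SDs are fixed at their sample estimates (no hierarchical
re-estimation), matching how group summaries are reported and used.

Four named TEF scenarios span the low/high extremes of published
collagen-diet enrichment for humans and metabolically similar omnivores:
ε¹³C ∈ {+3, +5}‰ × ε¹⁵N ∈ {+3, +6}‰, all with SD 0.5‰. Running all four and
comparing outputs is the intended use; the mixing-polygon screen
(`geometry.tef_plausibility`) helps rule scenarios out before fitting.

## Sampling

Random-walk Metropolis on the additive log-ratio (ALR) transform of the
simplex (reference coordinate last). The target density on ALR coordinates
is the likelihood times the Dirichlet prior times the ALR Jacobian
(∏_k p_k), which reduces to Σ_k α_k log p_k for the prior+Jacobian term.
The proposal is an isotropic Gaussian whose scale is adapted every 100
iterations during burn-in toward the 20–50% acceptance band (factor
`exp(1.5·(rate − 0.3))`, clipped to [1e-3, 10]); adaptation stops at the end
of burn-in, so retained draws come from a fixed kernel. Chains start from
independent N(0, 0.5) ALR draws; each chain's RNG is spawned from the master
seed via `SeedSequence`, so results are reproducible and chains independent.

Default run configuration is the "very short" setting (chain length 10 000,
burn-in 5 000, thin 5, 3 chains). The escalation ladder re-fits at
(50k/25k/25), (100k/50k/50) and (300k/200k/100) until the convergence
criteria pass; exhausting the ladder returns the last result explicitly
flagged non-converged, never a silent pass.

## Convergence and identifiability

- **Gelman–Rubin**: R̂ = sqrt(((n−1)/n·W + B/n)/W) per proportion on retained
  draws; pass requires R̂ < 1.05 for all proportions.
- **Geweke**: z comparing the first 10% window mean against the last 50%,
  with spectral-density-at-zero standard errors estimated by
  Bartlett-windowed autocovariances (lag window ≈ √window-length). Pass
  requires ≤ 5% of variables per chain with |z| > 1.96; with only four
  monitored proportions this means none, so chance escalation is common —
  that strictness is intentional and mirrors how the protocol is used.
  Calibration on iid chains of length 10 000 gives a type-I rate within the
  binomial band around 5% (the shorter the windows, the heavier the tails of
  the windowed-variance estimator; at the default run lengths the rate is
  slightly above nominal, which only makes escalation conservative).
- **Identifiability**: Pearson correlations between proportion draws; any
  pair below −0.7 is flagged indistinguishable. Isotopically close sources
  (e.g. the two marine groups) are routinely flagged — the correct reading
  is that only their *sum* is constrained, which is why marine/terrestrial
  aggregation is computed on per-draw sums rather than per-source intervals.

Credible intervals are equal-tailed quantile intervals (2.5/97.5 and 25/75
percentiles); the paper-style HPD alternative is not implemented.

## Corrections

Suess-effect: atmospheric δ¹³C_CO₂ has declined since ~1860, so modern
(collection year ≥ 1860) sample δ¹³C values are *raised* onto the
pre-industrial basis by adding `−6.48 − δ¹³C_CO₂(year)` (terrestrial) or
0.65× that (marine). The sign convention is fixed by physics: the Suess
effect depletes modern tissue, so comparability with archaeological material
requires adding a positive correction. δ¹⁵N is never Suess-corrected.
Archaeological records are exempt; a modern record whose year is missing
from the series is an error, not a skip.

Tissue offsets are additive per element with the ε = target − source
convention, so hair → collagen-equivalent conversion with the measured
collagen–keratin spacing adds (−0.3, +0.4)‰. The sign lives in the offset
table, not in code, so a site using the opposite convention just negates its
table. Originals are kept untouched and every adjustment is logged
(sample id, kind, magnitude).

## Frequentist components

- **KNNr**: statistic = total count of same-label points among each point's
  k nearest Euclidean neighbours (self excluded; distance ties broken by
  point index). p = (1 + #{perm ≥ obs})/(1 + n_perm) over seeded label
  permutations. Defaults k = 1, 9 999 permutations, axes in raw ‰
  (unscaled) — the smallest-k variant is the canonical form, and the test is
  exact-level by construction.
- **Wilcoxon rank-sum**: W is the Mann–Whitney U of x over y (R's
  convention: W(x,y) + W(y,x) = n_x·n_y); exact p for tie-free samples with
  min(n) ≤ 8, otherwise normal approximation with continuity and tie
  correction (scipy backend).
- **Kruskal–Wallis** with tie correction (scipy) and **Holm** step-down
  adjustment (statsmodels), both verified against hand-computed instances.
- **Generalized Shapiro–Wilk**: standardize by mean and inverse Cholesky
  factor of the covariance, apply univariate Shapiro–Wilk per transformed
  coordinate; MVW is the mean of the coordinate statistics, and the p-value
  refers the sum of squared normal deviates of the coordinate p-values to
  χ²_d. Calibration at α = 0.05 is verified by simulation.
- Convex hulls come from Qhull (scipy); point-in-polygon is a half-plane
  sign test with a 1e−9‰ boundary-inclusive tolerance, so values sitting on
  an edge do not flip with rounding.

## Synthetic data and what it does (not) show

The generator is the model run forwards. Default group layout (means ‰,
chosen inside the observed envelope δ¹³C ∈ [−26.5, −7.7], δ¹⁵N ∈ [−5.1, 19.4]):
terrestrial plants (−25, 5), terrestrial vertebrates (−21, 8), marine
invertebrates (−14, 11), marine vertebrates (−13, 16); SDs 1.0–1.5‰; %C ≈
40–44 for all groups, %N 2 (plants) vs 10–14 (animal tissue); generative TEF
(+3, +6)‰ with SD 0.5; 30 source samples per group and 35 consumers whose
true diets are Dirichlet(1,1,1,1) draws. These defaults are configuration,
not claims about any real assemblage.

Because consumers are sampled from the model's own process-error normal,
passing recovery tests demonstrates *internal* calibration of the sampler
and likelihood (coverage ≈ nominal is guaranteed for a correct
implementation, since true diets are drawn from the prior). It does not
demonstrate robustness to real-data violations: metabolic routing of
macronutrients, diagenesis, within-group concentration variation, or
non-normal source distributions are all outside the generator. The
enrichment-sensitivity experiment quantifies one mis-specification —
fitting with ε¹³C 2‰ above the generative value biases the recovered marine
fraction toward terrestrial by roughly the shift divided by the
marine–terrestrial δ¹³C gap, and the 50% intervals of matched fits cease to
overlap for most mid-diet consumers.

The recovery harness fits against the design's true source distributions
rather than re-estimated ones; this isolates sampler/likelihood calibration
from source-estimation noise (which, at 30 samples per group, would
contribute ~0.2‰ standard error to the means — small but not zero).

## Numerical choices and edge cases

- Proportions are floored at 1e−300 before logs; a zero-variance mixture
  supports only its own mean (log-likelihood −inf elsewhere).
- Consumer ranking ties (equal δ¹³C) break lexicographically by id, making
  report ordering deterministic.
- Degenerate chains (zero within-chain variance) fail R̂'s preconditions and
  are reported as non-converged rather than raising out of the protocol.
- The permutation and Monte-Carlo tests use fixed seeds throughout; the
  KNNr seed is mandatory (no silent global-state randomness).
- Problem sizes in the test suite and acceptance script (200-consumer
  recovery at 6k-iteration chains, 60-consumer sensitivity runs, 500-replicate
  calibration nulls, 0.01-step grid oracle) were chosen as the smallest runs
  whose Monte-Carlo error is well below the tolerances being checked.

## Known limitations

- No residual error term, hierarchical consumer effects, explicit
  metabolic-routing weights, or posterior TEF estimation — all deliberately
  out of scope.
- Per-source posteriors for isotopically close groups are prior-dominated;
  only aggregated fractions should be interpreted when the identifiability
  check flags a pair.
- The Geweke gate is strict for 4-variable models (any |z| > 1.96 fails a
  chain), so escalation beyond the first rung is frequent even for healthy
  chains; treat escalation level as cost, not as evidence of pathology.
- XLSX inputs are not parsed; tables are exchanged as canonical CSV.
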