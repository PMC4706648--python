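# Methods notes

This note documents the statistical model behind each analysis stage, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data calibration does and does not demonstrate.

## Data model

The observed unit is a higher taxon (family) with minimum and maximum adult
body length (mm), described species richness, and a major-clade label.
Species within a family are modelled as lognormal in size, so all analysis
happens on the natural-log scale in units of ln(mm), and the within-family
distribution is normal and symmetric there.

* **Tip mean.** Mean-of-logs `(ln min + ln max)/2`. Symmetry of the log-scale
  distribution makes this the natural point estimate given only the range.
* **Corrected richness.** `n + 2` everywhere. Monotypic families have
  min = max and would otherwise have an undefined spread; adding 2 is ad hoc
  but keeps those lineages (and their phylogenetic information) in the
  analysis rather than dropping them.
* **Tip SD.** Range-based estimation whose rule depends on sample size:
  corrected richness ≤ 15 uses the three-point small-sample estimator
  `sqrt([(a − 2m + b)²/4 + (b − a)²]/12)` on the log limits; 16–70 uses
  `range/4`; ≥ 71 uses `range/6`. Only a range (no median) is observed, and
  the symmetric-lognormal assumption forces the median to the midpoint of
  the log range, collapsing the small-sample estimator to `range/√12`; the
  full three-term form is exposed (`median_offset`) for callers with a
  median. Two boundary conventions had to be fixed: the size classes leave
  15 unassigned, which we give to the small-sample branch; and the rules are
  applied to *corrected* richness, since the +2 correction exists precisely
  to make the SD rules well-defined for tiny clades. Both switches are
  recorded in the run log.
* **Tip SE.** `sd/√(n_corrected)`, treating corrected richness as the sample
  size, floored at 1e-6 ln(mm) (configurable) so that `diag(se²)` never
  makes a covariance matrix exactly singular when min = max.

## Phylogenetic signal

Blomberg's K with measurement error. Tip covariance `V = σ²C + diag(se²)`
with C the Brownian shared-ancestry matrix (entries = root-to-MRCA path
lengths, My). σ² and the phylogenetic mean are estimated by maximizing the
MVN likelihood — the mean is profiled analytically by GLS, σ² by a bounded
scalar search on log σ² over [1e-12, 1e4] with 1e-10 tolerance. K is the
observed-to-expected MSE ratio computed on `W = C + diag(se²)/σ²`; with
se = 0 this is exactly the original statistic, and on a star tree it equals
1 identically for any data (a test pins this at 1e-10).

Significance: permutation test on the variance of standardized independent
contrasts, with each terminal branch inflated by `se_i²/σ̂²`. The (value,
se) pair is permuted together — a tip's uncertainty travels with its datum.
The inflation uses the observed-data σ̂² for all permuted replicates;
re-estimating σ² per permutation is a defensible alternative but makes the
null statistic depend on a nested optimization, and at the replicate counts
used here the difference is negligible. p-values use the add-one convention
`(1 + #{perm ≤ obs})/(n_perm + 1)`, so the floor is 1/(n_perm+1), never 0.

## macroCAIC richness contrasts

Trait contrasts follow the standard pruning recursion (contrast
`(x_L − x_R)/√(v_L + v_R)`, nodal values branch-length-weighted, daughter
branches extended by the averaging term). Richness at an internal node is
the *sum* of descendant tip richness, and richness contrasts are not
divided by branch lengths. Each row is oriented so the trait contrast is
non-negative; exact trait ties are oriented by a seeded coin flip (measure
zero for continuous data). Contrasts use corrected (+2) richness.

Regression through the origin: slope `Σxy/Σx²`, residual df n−1, R² and
adjusted R² under the uncentered no-intercept convention (validated against
statsmodels OLS without a constant).

Parametric bootstrap: per replicate every tip value is redrawn
`Normal(log_mean, scale)`; the default scale is the terminal log-SD
(draws from the estimated terminal distribution), with `draw_scale="se"`
available as the alternative reading (draws of the *mean's* sampling
error); the mode is recorded in output metadata. Null replicates permute
whole tip distributions (mean and scale together) across tips before
drawing, so bootstrap and null replicates carry comparable noise.
Significance requires the 2.5–97.5 % slope intervals of the two
distributions to be disjoint — a deliberately conservative rule. The
default is 50,000 replicates; the test suite and calibration experiments
use reduced counts (2,000) after checking that interval endpoints are
stable to ~2 significant figures at that size. Because contrasts are linear
in tip values, the bootstrap is vectorized as one matrix product per chunk
of replicates.

## Evolutionary models

All six models are MVN models for the tips with mean `z0·1` and covariance
`σ²·V_model + diag(se²)`:

| model | V_model | shape | bounds |
|---|---|---|---|
| BM | C | — | — |
| EB | `(e^{aC} − 1)/a` | a | `[−10/T, −1e-6]` |
| delta | `C^δ`, rescaled to depth T | δ | `[1e-5, 3]` |
| SSP | `e^{−2α(T−C)}(1 − e^{−2αC})/(2α)` | α | `[1e-8, 50/T]` |
| lambda | off-diagonals × λ | λ | `[0, 1]` |
| WN | I | — | — |

Decisions worth spelling out:

* **SSP** is the stationary-peak Ornstein–Uhlenbeck process on an
  ultrametric tree with the optimum equal to the root state — 3 parameters
  total (σ², α, z0). It requires an ultrametric tree and refuses others.
* **delta rescaling.** `C^δ` changes the tree depth, which would silently
  change the meaning of σ²; the default rescales so the maximum diagonal
  equals T (switchable via `rescale_depth=False`).
* **EB's upper bound** is −1e-6 rather than 0, so EB never degenerates into
  an unidentifiable BM duplicate; estimates pinned there are flagged
  `at_bound` (the true magnitude may be smaller). A side effect is that
  EB's maximum likelihood can sit ~1e-6 *below* BM's instead of exactly
  nesting it; the tests allow for this.
* **Optimization.** z0 is profiled by GLS at every step. σ² and the shape
  are optimized by L-BFGS-B on (log σ², shape), with δ and α
  log-transformed; 5 seeded restarts by default (a moment-based start plus
  random draws); convergence failure after all restarts raises rather than
  returning silently.
* **AICc** uses n = number of tips: `−2ℓ + 2k + 2k(k+1)/(n−k−1)`, k = 2 for
  BM/WN and 3 otherwise; it is refused (not extrapolated) when n ≤ k+1.
  Akaike weights are normalized relative likelihoods. The favoured model is
  the lowest-AICc one unless a model with fewer parameters lies within 2
  AICc units, in which case the simplest such model is preferred.

BM ancestral states are joint-ML (= GLS conditional expectations)
`z0 + σ²c'V⁻¹(x − z0)` with c the node-tip shared path lengths; with se = 0
they are independent of σ², so the closed form is used. The PGLS of tip SD
on tip mean uses the Brownian covariance through statsmodels GLS (slope SE,
t on n−2 df).

## Synthetic data and what the calibration shows

`simulate_yule_tree` grows a crown-conditioned pure-birth tree; with k
lineages the next split waits `Exp(λk)`, and one final `Exp(λn)` epoch is
appended, making the expected crown age `Σ_{k=2..n} 1/(λk)` (checked by
simulation against the closed form). `simulate_trait` draws once from the
model MVN (eigendecomposition, robust to σ² = 0).
`aggregate_to_families` slices the tree at a chosen age; each crossing
lineage founds a family whose record keeps only exp(trait) min/max and the
member count. Family tips keep their full depth to the present
(representative-species pruning) so the family tree is ultrametric — this
matches data where terminals are extant families, rather than truncating at
family crown ages.

The generator reproduces the *statistical structure* the analysis assumes:
lognormal within-family spread is replaced by whatever the trait model
implies, richness is exact rather than an undercount, families are true
clades, and the tree is known without error. Passing calibration therefore
shows the estimators are correct under their own assumptions; it says
nothing about taxonomic description bias, non-lognormal within-family
distributions, or phylogenetic uncertainty in real compilations.

Calibration experiments (seeded, rerun by `scripts/acceptance.py` and the
test suite; sizes chosen to give Monte-Carlo error comfortably inside the
decision margins):

* 200 datasets, 100-tip Yule trees, BM traits (σ² = 0.01, se = 0): mean K
  ≈ 0.96 and mean ML λ ≈ 1.00 — both near the BM expectation of 1.
* The same with iid tip values: mean K ≈ 0.06, mean λ ≈ 0.01 — near the
  no-signal expectation of 0.
* 200 family-level experiments with richness independent of the trait:
  the bootstrap-vs-null disjointness rule fires in well under 7 % of
  experiments at 2,000 replicates (nominal 5 %).
* 100 BM datasets at 300 tips: σ² recovered with |median bias| < 10 %.

## Known limitations

* Single-regime models only: no rate shifts on branches, no multi-optimum
  OU, no Bayesian machinery.
* The SD rules treat all within-tip variance as taxonomic under-sampling;
  specimen-level variation and dimorphism are not separable from it.
* The randomization test fixes σ̂² across permutations (see above).
* Polytomies must be resolved (seeded, zero-length) before contrast-based
  analyses; results at polytomy-heavy nodes depend on that resolution only
  through contrast bookkeeping, not through the covariance matrix.
* The PDI metric is bounded and therefore less sensitive than RRD for very
  asymmetric richness splits; both are reported by the pipeline.
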