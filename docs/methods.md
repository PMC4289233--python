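# Methods

Statistical definitions, model parameters, generator limitations and
numerical conventions for the `ratiometric` package.

## 1. Pairwise statistics

### Ratiometric association (RA)

For a gene pair (A, B) with per-sample abundances `a_i`, `b_i`:

- ratios `r_i = a_i / b_i` and `s_i = b_i / a_i` are formed over the
  samples where **both** values are strictly positive (a ratio is
  undefined at zero);
- `CV(A/B) = sd(r) / mean(r)` and `CV(B/A) = sd(s) / mean(s)`, with the
  sample standard deviation (`ddof = 1`, configurable via
  `MeasureConfig.cv_ddof`);
- `Δ_CV = |CV(A/B) − CV(B/A)|` is the stringency-of-fit statistic. It is
  invariant to swapping the genes and to rescaling either gene by a
  positive constant;
- a pair is **ratiometric** when `Δ_CV < delta_cv_threshold` (default
  0.01 for bulk panels; `MeasureConfig.for_single_cell()` switches to
  0.025). An optional `stability_bound` can be conjoined with the gate;
- **stability** = `max(CV(A/B), CV(B/A))` (or their mean, via
  `stability_rule`) ranks gate-passing pairs, smaller = stronger.

Zero handling: if fewer than `min_used_fraction` (default 0.95) of the
samples have both genes positive, the ratio statistics are not evaluable
and the pair is reported with `ra_evaluable = False` and NaN ratio
fields rather than dropped; Pearson, Spearman and MI always use all
samples.

### Baselines

- Pearson `r` and `r²` (sample correlation).
- Squared Spearman rank correlation (average ranks for ties).
- Plug-in mutual information on equal-frequency bins: each margin is
  discretised into `mi_bins` (default 4) equal-frequency bins and
  `I = Σ p log2(p / (p_a p_b))` computed from the joint bin histogram.
  With 4 bins the statistic lives in [0, 2] bits. Binning uses min-rank
  assignment, so tied values always share a bin and a tie group spanning
  a nominal bin boundary falls in the **lower** bin; for distinct values
  this coincides with plain rank binning. MI requires at least
  `mi_bins` samples; with heavy ties fewer than `mi_bins` distinct bins
  may be occupied, which only lowers the estimate.

No bias correction is applied to the plug-in MI; at the panel sizes used
here (≥ 100 samples, 16 joint cells) the bias is small and identical
across pairs, so rankings are unaffected.

## 2. All-pairs scan and stringency sweeps

`all_pairs` computes every unordered pair (gene ids sorted
lexicographically within a pair) using per-anchor-gene vectorized
blocks: `np.corrcoef` for Pearson and for Spearman on ranks, bincount
joint histograms for MI, and masked ratio sums for the CVs. Constant
genes are rejected up front (correlation undefined).

A **stringency sweep** divides a method's statistic range into 100 equal
threshold steps and materialises the nested graph series G_1 ⊆ … ⊆
G_100 (vertices are genes with at least one included edge; degree-0
genes are excluded). Per-pair first-inclusion steps are computed
arithmetically, so edge/vertex counts for all 100 steps cost one pass:

| method | swept statistic | range | step `k` accepts |
|---|---|---|---|
| PE / SP | r² (or ρ²) | 1 → 0 | `r² ≥ 1 − k/100` |
| MI | I | log2(mi_bins) → 0 | `I ≥ span·(1 − k/100)` |
| RA (`delta_cv` mode) | Δ_CV | 0 → 1 | `Δ_CV ≤ k/100` |
| RA (`gated_cv` mode) | stability of gate-passing pairs | 0 → observed max | `stab ≤ span·k/100` |

`delta_cv` mode sweeps the gate itself; `gated_cv` mode fixes the gate
and sweeps the stability ranking, which is the mode that concentrates
tight pathways into the smallest graphs.

Rankings (`rank_pairs`) break ties deterministically via `np.lexsort`:
RA ascending by (stability, Δ_CV, gene ids) over gate-passing pairs;
PE/SP descending by (r², |r|); MI descending by (I, r²).

Derived analyses: `inclusion_profile` (percent of genes included per
step), `select_graph_at_size` (most stringent step reaching a target
vertex/edge count), `method_overlap` (exclusive Venn regions of 2–3
size-matched graphs), `measure_correlation_matrix` (pairwise-complete
correlations of the six per-pair statistics), `invariance_diagnostic`
(per-gene expression CV vs best gated stability), `two_regime_flag`
(does removing the jointly-high sample subgroup drop r² by more than
`r2_drop`?), `ranking_consistency` (top-k overlap fractions between two
rankings).

## 3. Enrichment

- **Annotated-edge fraction**: percent of a graph's edges with both
  endpoints annotated (optionally requiring both endpoints in one
  common set).
- **Within-pathway recovery**: within-pathway edge counts of the graphs
  selected at a series of target vertex sizes.
- **Permutation null**: pathway labels are re-drawn preserving the
  pathway's expression composition — genes are binned by mean
  expression into `match_bins` equal-frequency bins (`pd.qcut`) and
  each permuted set draws the same number of genes from each bin. The
  envelope reports the null mean/min/max over `n_perm` draws; an
  undersized bin raises an error naming the bin.
- **Ontology aggregation**: terms whose own detected-gene count is at
  least `min_size` (default 200) are category seeds; every smaller term
  merges into its nearest large ancestor (BFS distance in the
  child→parent DAG; ties broken by fewest detected genes, then
  lexicographic id). Small terms with no large ancestor roll up into
  their root, which is flagged as undersized.
- **Category enrichment**: hypergeometric upper tail
  `P(X ≥ k) = hypergeom.sf(k−1, N, K, n)` with Bonferroni correction
  (`p·n_tests`, capped at 1), enriched when corrected p ≤ 1e-4.
- **CV profiles**: per-gene expression CVs grouped by pathway, compared
  with Welch's unequal-variance t-test.

## 4. Simulations

### Range restriction (`simulate_range_restriction`)

`b ~ N(500, sd²)` with `sd` swept 0–125 in steps of 5 (26 values,
non-positive draws rejected and redrawn), `a = 2b + u`,
`u ~ N(0, 50²)`, 100 samples, 10 replicates per SD. Reports per-SD mean
and standard error of R², Spearman ρ², MI, CV(A/B), CV(B/A), Δ_CV.
Degenerate constant-B runs (SD 0) report R² and MI as 0 by convention.
The generative link is fixed; only B's range changes — correlation-style
measures collapse with shrinking range while the ratio CV stays near the
noise floor `noise_sd/(slope·mu_b) ≈ 0.05`.

### Bivariate normal (`simulate_bivariate_normal`)

Bivariate normal with means 200/200, generative correlation 0.47, equal
SDs 10–80 in steps of 10, 1000 runs × 1000 observations per SD. Each
run contributes its sample Pearson r and whether it meets the
ratiometric definition (Δ_CV < 0.01 **and** stability ≤ 0.135;
non-positive samples excluded from the ratios). By the
multivariate-normal property the sample r is constant in the SD; the
ratio stability grows like `(sd/mean)·sqrt(2(1−ρ))`, so the ratiometric
fraction collapses once the per-gene CV passes ≈ 0.1 (the theoretical
stability crosses 0.135 between SD 20 and SD 30 at these parameters).

### Independent null (`simulate_independent_null`)

Pairs of independent log-normal genes (log-SD 0.4); reports the gate's
false-positive rate with its binomial Monte-Carlo SE.

### Fixture generator (`generate_fixture`)

Seeded synthetic panel (default 200 samples) with planted classes:

- `ratiometric` (50 pairs): `a = c·b·(1+ε)`, `ε ~ N(0, 0.05²)`
  (redrawn if ≤ −1), base gene log-normal with log-SD 0.1 and mean
  log-uniform over 10^0.5–10^2.5; the constant `c` (log-uniform
  10^±0.7) is recorded in the truth table.
- `wide_correlated` (50): `a = 2b + u` on a wide-range base (log-SD
  1.2), floored at `0.01·b` to stay positive — high R², loose ratio.
- `two_regime` (50): independent low-expression bulk plus a 10% sample
  subgroup jointly high — correlation driven by the subgroup alone.
- 500 independent background genes (log-SD 0.4).

Limitations: genes are independent across pairs (no shared covariance
or batch structure), noise is homoscedastic within a class, there are
no zero counts or dropout (zero handling is exercised by dedicated unit
tests instead), and abundances are continuous rather than count-based.
The generator targets the structural claims (gate recovery, ranking
separation, sweep shape), not distributional realism.

## 5. Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`; every
  simulation and the fixture generator are byte-deterministic given the
  seed, and CLI outputs embed their options in a `#` header so equal
  invocations yield equal bytes.
- Rejection sampling (not truncation or clipping) keeps abundances
  strictly positive without distorting the distribution shape near
  typical parameters; rejection counts are reported in
  `frame.attrs["n_rejected_draws"]`.
- Sweep inclusion uses exact integer step arithmetic
  (`ceil(stat/step_width)` style) rather than repeated threshold
  comparisons, making the 100 nested graphs cheap and exactly
  consistent with direct recounts (asserted by the test suite).
- Vectorized CV computation uses the `E[x²] − E[x]²` form with a
  non-negativity clamp for float round-off; the scalar reference path
  (`cv_ratio`) uses `np.std` directly, and the two are asserted equal
  to float tolerance.
- Monotone-trend acceptance checks on Monte-Carlo means use the
  Spearman rank correlation of the means against the swept parameter
  (threshold 0.97) plus a relative-spread bound (sd/mean < 0.10 for the
  flat CV), rather than strict per-step monotonicity, which a finite
  replicate count cannot guarantee; the thresholds were fixed before
  the acceptance runs.

## 6. Scope of validation

Desk-scale acceptance is simulation- and property-based (see
`tests/test_acceptance.py` and `scripts/acceptance.py`). Published
dataset-scale figures (thousands-of-genes panels, single-cell batch
reproducibility percentages) require downloading the original
expression panels and are **not** reproduced here; the library's
filtering, scanning, sweep and enrichment entry points accept such
panels unchanged, so they can serve as optional integration checks when
the data are available.
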