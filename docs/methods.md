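# Methods

## Co-occurrence networks and tightening

For each successional stage, the network is built from exactly that
stage's samples (the design is 3 sites × 3 subplots = 9 samples per
stage; no pooling across stages). The steps are:

1. **Occurrence filter.** Taxa with abundance > 0 in fewer than two
   samples of the stage are removed. A taxon seen once cannot contribute
   a meaningful rank correlation; a taxon absent from the stage carries
   no information at all.
2. **Spearman matrix.** Pairwise Spearman rank correlations with average
   ranks for ties, computed as rank-transform followed by a Pearson
   product-moment matrix (the two are definitionally identical). A
   zero-variance rank vector — a taxon with identical values in every
   sample, which binarisation routinely produces — makes the correlation
   undefined; undefined entries are marked (NaN) and treated as
   non-edges, never propagated into counts.
3. **Thresholding.** Pairs with defined ρ strictly greater than τ = 0.9
   form edges; negative correlations never do. Strictness is
   configurable (`strict=False` gives ρ ≥ τ); with continuous abundances
   the choice only matters at exact ties.
4. **Connectance.** `100 · n_strong / n_possible`. Two denominator
   policies are implemented because "all possible connections" admits two
   readings: `all_pairs` (every unordered pair of retained taxa,
   N(N−1)/2, the default) and `between_only` (only pairs spanning two
   functional groups, Σ_{a<b}|a||b|). The policy used is recorded in
   every summary. Undefined correlations stay in the denominator, so
   n_possible depends only on which taxa were retained.
5. **Interaction strengths.** For each unordered pair of functional
   groups, strong pairs divided by possible pairs between them. Each
   group's pairing with itself is computed too but flagged as not
   displayed, matching the convention of calculating within-group links
   without drawing them.

Because everything downstream of the ranks is rank-based, the pipeline is
invariant under sample reordering and under any strictly monotone
per-taxon transform of the abundances. This is what lets heterogeneous
units (sequence reads, microscope counts, % plant cover) share one
correlation matrix; no cross-taxon normalisation is applied. An optional
total-sum scaling switch exists for workflows that want per-sample
relative abundances, but it cannot change any rank-based result.

Whether plants and protists enter the matrix is left to the caller
(config switches in the readers); the defaults follow the convention of
including plant % cover as one more taxon group and excluding protist
counts that lack full replication.

Shannon diversity `H = −Σ p_i ln p_i` over positive proportions is
provided for community-evenness summaries.

## Isotope accounting

- **Scales.** δ = (R_sample / R_ref − 1) · 1000 (per mil);
  atom% = 100 · R / (1 + R); R = R_ref (δ/1000 + 1). Reference ratios
  default to R_VPDB = 0.0111802 (¹³C/¹²C) and R_air-N₂ = 0.0036765
  (¹⁵N/¹⁴N), the IAEA-recommended values; both are overridable. The
  δ ↔ atom% conversions are mutually inverse to better than 1e−12
  relative error across δ ∈ [−900, 10000] ‰.
- **Calibration** is ordinary least squares of certified on measured δ
  (not inverse regression), using the certified reference values of
  USGS40 (δ¹³C −26.39, δ¹⁵N −4.52), USGS41 (+37.63, +47.57), NIST8542
  (δ¹³C −10.45) and USGS25 (δ¹⁵N −30.41). With exactly two standards the
  fit is the exact two-point line, so corrected standards reproduce their
  certified values to rounding.
- **Element content** comes from a linear standard curve of detector
  area against known element mass, built from weighed amounts of
  sulfanilamide (41.84% C, 16.27% N), nicotinamide (59.01% C, 22.94% N)
  and L-aspartic acid (36.09% C, 10.52% N).
- **Excess** is labelled minus control atom%. Negative excess (label
  below control, i.e. measurement noise around zero enrichment) is
  preserved and flagged in budgets, and only floored to zero when
  fractions are formed — hiding it earlier would silently bias budgets;
  flooring later keeps fractions interpretable.
- **Biomarkers.** Bacterial PLFA: i14:0, i15:0, a15:0, i16:0, 16:1ω7t,
  17:1ω7, a17:1ω7, i17:0, cy17:0, 18:1ω7c, cy19:0. Actinomycetes:
  PLFA 10Me16:0. Fungi: PLFA 18:2ω6,9. AMF: NLFA 16:1ω5. Names are
  normalised (ω → w, comma/dot variants merged) before lookup; unmapped
  fatty acids are dropped with a warning since general lipids carry no
  taxonomic signal. The 15N in microbial biomass is *not* split between
  fungi and bacteria — lipid markers cannot do that — so nitrogen budgets
  stop at the whole-compartment level.
- **Channel partition.** Fractions are each pool's share of the summed
  (floored) excess ¹³C and always sum to 1; root-scaled values divide by
  the total labelled carbon in the roots instead, which makes stages with
  different root label uptake comparable. Microbial pools are evaluated
  1 day after the pulse, consumers at 1 week, predators at 2 weeks — the
  time point of peak incorporation for each trophic level; the mapping is
  configurable.
- **F:B ratios** are reported both as per-sample mean ± s.d. and as the
  ratio of pooled sums; the two are generally different and both are kept
  visible.

## Synthetic data

**Community generator.** Within each functional block and stage, taxon
values are `z = √r·u + √(1−r)·ε` with a shared per-sample latent `u` and
independent noise `ε`, mapped through a lognormal marginal
(`abundance = 100·e^z`). Spearman correlation is invariant under the
monotone marginal map, and for a Gaussian copula the population Spearman
equals `(6/π)·arcsin(r/2)`, so the latent Pearson correlation is set to
`r = 2·sin(π·ρ_target/6)` to hit a requested within-block Spearman
ρ_target. Empirically (50-seed checks in the test suite) the realised
mean pairwise correlation tracks the target well at 9 samples; censoring
(below) biases it slightly downward, which is tolerated rather than
re-calibrated.

Occupancy — the probability a taxon is detected in a sample — is
implemented as left-censoring at a detection limit: values with latent
`z` below the (1 − occupancy) normal quantile become zeros. Censoring is
driven by the same latent variable, so presence–absence patterns inherit
the block structure. This is deliberate: with independently injected
zeros, binarised vectors would be i.i.d. Bernoulli and a
presence–absence analysis could never see the planted correlation
structure, making robustness checks vacuous. The cost is that zeros are
always the smallest abundances (no erratic dropout of abundant taxa).

Defaults: 3 stages × 9 samples, six functional blocks (39 taxa),
within-block Spearman targets (0.3, 0.7, 0.7) across stages — a
recent → mid tightening transition followed by a plateau — and occupancy
0.9. One global seed drives all randomness; generated files embed their
spec in a header comment.

**Tracer generator.** Each compartment's true excess atom% is its
transfer fraction times the trophic level's total; labelled replicates
carry that excess times multiplicative lognormal noise `exp(N(0, σ))` on
top of a natural-abundance baseline (δ¹³C = −27 ‰, δ¹⁵N = +2 ‰), and
controls sit at the baseline. Noise is applied to the enrichment signal,
not the baseline: natural-abundance variation between intact cores is
small relative to tracer variability, and putting noise on total atom%
would conflate the two. Defaults: root excess 0.8 atom%, microbial split
0.35/0.50/0.15 (bacteria/fungi/AMF — the pattern of a recently abandoned
grassland where fungi capture about half the root-derived carbon),
σ = 0.05, 9 replicates. With σ = 0 the pipeline recovers the fractions
exactly; at σ = 0.05 the mean absolute fraction error over 100 seeds is
well under 0.02.

**What the generator does not emulate:** real taxonomies, absolute field
abundances, compositional (closed-sum) artefacts of sequencing data,
spatial autocorrelation between subplots, and label recycling between
pools. Passing tests therefore demonstrate that the statistics recover
structure the generator plants, not that the field study's effect sizes
are correct.

## Numerical and design choices

- Connectance is exact integer arithmetic times 100; the published
  count pairs reproduce the published percentages at 3 decimals.
- The published strong/possible *counts* themselves are not reproducible
  without the raw data and the exact subgroup partition, so the package
  reproduces the connectance arithmetic, not the counts.
- Spearman at n = 9 samples is coarse; an edge at ρ > 0.9 needs
  near-perfect rank agreement. Tests that compare stage orderings
  therefore average over ≥ 50 seeds (problem sizes chosen to keep the
  whole suite fast: 39-taxon communities, 8 × 9 oracle tables, 100-seed
  tracer batches).
- Presence–absence robustness is checked in a regime with real absences
  (occupancy 0.7) and a strong tight-stage contrast (block Spearman 0.2
  vs 0.9): binarisation of a near-saturated table yields mostly constant
  vectors, whose correlations are undefined by construction, so no
  binary analysis — here or on real data — can work without absences.
- Ties use average ranks throughout, matching the common statistical
  convention.

## Known limitations

- Networks are correlation-based co-occurrence, not inferred
  interactions; indirect correlations are not deconvolved.
- No compositional correction (e.g. CLR) is applied before ranking;
  with relative sequence abundances this can induce spurious negative
  correlation, which the positive-edge rule partly shields against.
- The isotope module does no peak integration or drift correction beyond
  the linear standard curve; inputs are assumed to be per-compartment
  δ or atom% values.
- Multi-factor significance testing of stage effects (nested ANOVA/GLM,
  PERMANOVA and relatives) is out of scope; the package emits tidy
  per-group tables ready for any statistics tool.
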