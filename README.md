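# soilweb

Tools for two linked questions about soil communities on land recovering
from agriculture:

1. **Does the belowground network "tighten" over succession?** Given a
   taxa × samples abundance table spanning a chronosequence of recently,
   mid-term and long-term abandoned fields, `soilweb` builds one
   co-occurrence network per successional stage (Spearman rank
   correlations over the stage's samples, thresholded at ρ > 0.9,
   positive correlations only) and quantifies tightening as
   **connectance** — strong correlations as a percentage of all possible
   taxon pairs — plus group-level **interaction strengths** (the share of
   pairs between two functional groups exceeding the threshold).

2. **Where does freshly fixed carbon go in the soil food web?** From a
   dual-label (¹³C/¹⁵N) pulse-chase experiment, `soilweb` handles the full
   isotope bookkeeping: δ‰ ↔ isotope ratio ↔ atom% algebra, calibration
   of measured δ values against USGS/NIST reference materials, excess
   enrichment over unlabelled controls, PLFA/NLFA biomarker aggregation
   into bacterial / actinomycete / fungal / mycorrhizal pools, F:B ratios,
   and the partitioning of root-derived carbon over the bacterial, fungal
   and AMF channels, scaled to the total labelled carbon in the roots.

The statistics in symbols: connectance for a stage is
`C = 100 · n(ρ > τ) / n(possible pairs)` with τ = 0.9; atom percent is
`atom% = 100 · R / (1 + R)` with `R = R_ref · (δ/1000 + 1)`
(R_VPDB = 0.0111802 for carbon, R_air-N₂ = 0.0036765 for nitrogen);
excess is `atom%(labelled) − atom%(control)`; channel fractions are each
microbial pool's share of the summed excess ¹³C, with root-scaled variants
`excess(pool) / excess(roots)`.

A synthetic-data module generates successional communities with tunable
within-block correlation (a Gaussian-copula construction whose Spearman
target survives the lognormal marginal transform) and tracer experiments
with known transfer fractions, so every pipeline stage is testable
end-to-end with ground truth.

## Worked example

```python
import soilweb as sw

# a 3-stage community, 9 samples per stage, with block correlation
# (0.3, 0.7, 0.7) encoding a recent -> mid tightening transition
table = sw.generate_abundance(sw.CommunitySpec(seed=1))
print(sw.CooccurrenceNetwork(table, tau=0.9).fit().summary())
```

```
Co-occurrence network tightening summary
threshold tau = 0.9 (strict), policy = all_pairs, abundance data
 stage  n_taxa  n_strong  n_possible  connectance_pct    policy   tau
recent      39         2         741            0.270 all_pairs 0.900
   mid      39         7         741            0.945 all_pairs 0.900
  long      39         8         741            1.080 all_pairs 0.900
```

Connectance roughly triples from the recent to the mid stage and then
plateaus — the network-tightening signature the generator planted.

```python
measurements, truth = sw.generate_tracer(sw.TracerSpec(seed=1))
print(sw.TracerExperiment(measurements).fit(element="C").summary())
```

```
Tracer budget (C), root excess = 0.809174
    pool  excess  fraction  root_scaled  floored
bacteria  0.0700    0.3519       0.0864    False
   fungi  0.0981    0.4935       0.1212    False
     AMF  0.0307    0.1545       0.0380    False
F:B ratio of excess label: 1.4023
```

About half of the microbially captured carbon sits in the fungal channel,
recovering the generator's true fractions (0.35 / 0.50 / 0.15) from noisy
replicate measurements.

The same pipelines are available from a shell:

```sh
soilweb simulate community --seed 1 --out comm.tsv
soilweb network --abundance comm.tsv --summary summary.tsv --out edges.graphml
soilweb simulate tracer --seed 1 --out tracer.tsv --truth truth.yaml
soilweb isotope --measurements tracer.tsv --out budget.tsv
```

Every run writes a `.manifest.json` beside its output (arguments, package
version, input checksums) so results can be reproduced from artifacts
alone.

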