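# varprior

Candidate-gene prioritization for small family-based sequencing studies,
built around four pieces that are usually welded together ad hoc:

1. **Pedigree-aware variant filtering** — classify variants against a gene
   model (coding exon > UTR > intron > intergenic, strand-aware UTR sides),
   extract the recessive inheritance pattern (homozygous-alternate in every
   affected child, heterozygous in every parent of an affected child), and
   filter on minor-allele frequency (MAF) and predicted deleteriousness of
   exonic variants.
2. **Seed-based network propagation** — rank all genes in a weighted
   interaction network (STRING-style edge lists) by propagating prior mass
   from a binary seed set, with five kernels:

   * random walk with restart: `s_{t+1} = (1−r) Pᵀ s_t + r p₀`
   * heat-kernel diffusion: `s = exp(−t (I − Pᵀ)) p₀`
   * PageRank with priors (restart walk with damping `d`, `r = 1−d`)
   * HITS with priors (prior-blended hub/authority updates)
   * K-step Markov: `s = Σ_{k=1..K} (Pᵀ)^k p₀ / K`

   where `P` is the row-stochastic transition matrix and `p₀` the normalized
   seed vector. Significance per gene is an **empirical permutation p-value**:
   the seed-mass assignment is permuted uniformly over all nodes, scores are
   recomputed, and `p = #(permuted ≥ observed) / n_perm` (ties count against
   significance; default 10 000 permutations).
3. **Category enrichment** — upper-tail hypergeometric p-values with
   Benjamini–Hochberg correction, plus a one-sided Bayes factor comparing a
   `θ ~ Beta(a,b)` enrichment alternative truncated to `(p₀, 1]` against the
   background-rate binomial null.
4. **Cleft geometry** — shape descriptors of a protein cavity from a measured
   volume/area pair, `sphericity ψ = π^{1/3} (6V)^{2/3} / A` and
   `effective radius r_eff = 3V/A`, native-vs-mutant percent-change reports,
   and a two-probe rolling-sphere voxel method that extracts a cavity (the
   space a small probe can occupy but a large probe cannot reach from bulk
   solvent) directly from atomic coordinates.

A synthetic-data module generates nuclear-family VCFs, gene models and
scale-free interaction networks with *known planted structure* (exact
qualifying-variant counts, a dense module around the seed genes), so every
stage can be validated against ground truth.

## Worked example

The `analysis/` drivers run a complete synthetic study (seed 29). Step 01
simulates two families (two affected children each), 200 variants of which
12 carry the planted recessive pattern, and a 150-gene network whose planted
module surrounds the genes holding those variants (5 module genes are seeds,
5 are held out):

```text
$ python analysis/02_filter_variants.py
200 variants read; 12 match the recessive pattern (exactly the planted set)
region breakdown of pattern-matching variants:
  exonic      0
  utr5        1
  utr3        1
  intronic    4
  intergenic  6
12 remain at MAF = 0; 12 after the exonic deleteriousness filter

$ python analysis/03_network_prioritization.py
random_walk_restart over 150 genes, 5 seeds, 2000 permutations (seed 29)
5 genes significant at p < 0.05
held-out planted module genes:
  G007: rank 4, score 0.0515, p = 0.0415
  ...
5/5 held-out module genes pass the cut

$ python analysis/04_enrichment.py
query: 6 genes with surviving variants (G003, G007, G009, G013, G017, G023)
        category  size  overlap   p_value  adjusted_p  bayes_factor
  planted_module    10        6 0.0003537   0.0007073         156.1
```

The filter recovers exactly the planted set; every held-out module gene
ranks in the significant tier; and the planted-module category dominates the
enrichment table — the behaviour the pipeline is designed to exhibit when a
true signal is present. Step 05 reports the structural comparison: a cleft
shrinking from 807 Å³ / 442 Å² to 541 Å³ / 328 Å² loses 33 % of its volume
and 25.8 % of its surface area while its sphericity rises from 0.948 to
0.979 (effective radius 5.48 Å → 4.95 Å).

There is also a `varprior` CLI (`filter`, `netprank`, `enrich`, `cleft`,
`cleft-metrics`, `run`) wrapping the same library, e.g.:

```sh
varprior cleft-metrics --volume 807 --area 442
```

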