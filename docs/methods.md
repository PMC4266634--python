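# Methods

## Study design emulated

The package targets the two-arm design used in small family-based
sequencing studies of recessive birth defects: a *discovery arm* that
filters whole-genome variants by annotation and inheritance pattern, and a
*hypothesis arm* that ranks genes by their network proximity to a set of
pathway genes implicated a priori. Candidates are the genes that survive
both arms; a structural comparison of native and mutant protein forms
supports individual candidates.

## Variant filtering

Region classification assigns each variant the most severe class over all
overlapping isoforms (coding exon > 5'UTR > 3'UTR > intron > intergenic),
with the UTR side resolved by transcript strand. Coordinates are handled in
one place: VCF positions (1-based) are converted to the internal 0-based
half-open convention (BED) exactly once, at classification time.

The inheritance filter retains variants homozygous for the alternate allele
in **every** affected child and heterozygous in **every** parent of an
affected child, across all families; a missing genotype among those samples
disqualifies the variant, and homozygous-reference probands never qualify.
Phase is ignored. The MAF filter keeps variants at or below a threshold
(default 0, i.e. absent from the reference panel); unknown MAF is excluded
by default, relaxable by flag. The deleteriousness filter applies only to
exonic variants (labels `possibly_damaging` / `probably_damaging` pass;
`benign` or unknown are dropped); non-exonic variants pass through, since
the prediction is only defined for coding changes. All filters are pure
subset operations — idempotent and commuting — so composition order is
irrelevant, which the test suite checks as an algebraic property.

## Network propagation

The interaction network is an undirected graph with edge weights in [0, 1]
(STRING-style integer scores divided by 1000; edges below a configurable
threshold dropped; largest connected component retained by default). The
transition matrix `P` is the row-stochastic normalization of the weight
matrix; all kernels apply `Pᵀ`, which maps probability distributions to
probability distributions. Seeds enter as a binary membership vector
normalized to sum 1 (optional per-gene evidence weights are blended before
normalization).

Kernel defaults (all exposed in `params`):

| kernel | update / closed form | defaults |
|---|---|---|
| random walk with restart | `s ← (1−r) Pᵀ s + r p₀` | `r = 0.3` |
| heat kernel | `exp(−t (I − Pᵀ)) p₀`, truncated series | `t = 1`, 30 terms |
| PageRank with priors | restart walk with `r = 1 − d` | `d = 0.85` |
| HITS with priors | `a ← (1−β)·norm(Wᵀh) + β p₀` (and symmetrically for `h`) | `β = 0.3` |
| K-step Markov | `Σ_{k=1..K} (Pᵀ)^k p₀ / K` | `K = 6` |

Iterative kernels stop when the L1 change falls below 1e-9 or at 10 000
iterations, in which case the result is flagged unconverged rather than
silently returned. All five kernels conserve total mass (the HITS variant
because each update is a convex combination of L1-normalized terms), and all
produce nonnegative scores. Isolated nodes score 0 with p-value 1.

Permutation p-values reassign the seed-mass vector entries uniformly at
random over all nodes and rerun the propagation; for each non-seed gene,
`p = #(permuted score ≥ observed) / n_perm`. Ties — including ties at
floating-point precision, which are detected with an absolute 1e-12
tolerance — count against significance, so `p` can be exactly 0 when no
permutation reaches the observed score. The default `n_perm` is 10 000; an
optional `(k+1)/(n+1)` estimator bounds p away from zero. Everything is
deterministic under the supplied RNG seed. The significance cut retains
genes with `p < α` (default `α = 0.005`), sorted by `(p, −score)`.

## Enrichment

Per category with `K` members in a universe of `N` genes and a query of `n`
genes overlapping it in `k`, the p-value is the upper hypergeometric tail
`P(X ≥ k)`, BH-corrected across categories (Bonferroni available). The
Bayes factor compares a one-sided enrichment alternative against the sharp
null `θ = p₀ = K/N`:

    BF = ∫_{p₀}^{1} θ^k (1−θ)^{n−k} dΠ(θ)  /  p₀^k (1−p₀)^{n−k}

with `Π` a Beta(a, b) prior truncated to `(p₀, 1]` (default a = b = 1). The
one-sided support makes BF strictly increasing in `k` — every density point
`θ > p₀` contributes a likelihood ratio increasing in `k` — and yields
BF = 1 for an empty query. A two-sided (untruncated) Beta prior was
deliberately rejected: its BF is U-shaped in `k`, rewarding *depletion* as
well as enrichment, which is not the question this table answers. Note that
a query sitting exactly at the background expectation yields BF < 1 (the
sharper null wins, as it should by parsimony). Tissue- or
context-restricted enrichment is obtained by passing a restricted
background universe.

## Cleft geometry

From a measured cavity volume `V` (Å³) and surface area `A` (Å²):
`ψ = π^{1/3} (6V)^{2/3} / A` (1 for a sphere, < 1 otherwise, ≤ 1 + grid
error by the isoperimetric inequality) and `r_eff = 3V/A`. Native/mutant
comparisons report `100·(native − mutant)/native` per metric.

The grid method is a two-probe rolling-sphere construction (defaults: inner
probe 1.5 Å, outer probe 6.0 Å, spacing 0.5 Å; van der Waals radii from a
bundled element table, 1.7 Å fallback). For each probe radius `ρ`, the
probe-accessible region (`distance-to-atom-surface ≥ ρ`, computed exactly
per radius group with a KD-tree) is flood-filled from the box boundary and
dilated by `ρ` (Euclidean distance transform); its complement is the
solvent-excluded region for that probe. The cavity is the outer-probe
excluded region minus the inner-probe excluded region, plus any interior
void the inner probe can occupy but not reach from bulk. Because the probe
difference also sweeps up a thin film of shallow surface grooves, only the
largest connected component is reported by default. Volume is voxel count ×
spacing³; surface area is exposed-face count × spacing² × 2/3 — the exact
correction for face counting on an isotropically oriented boundary, whose
expected overcount is `E[|n_x|+|n_y|+|n_z|] = 3/2` (derived, not fitted).
On an analytic spherical void of radius 5 Å the method is within ~2 % in
volume and ~0.01 in sphericity at 0.25 Å spacing; accuracy degrades for
cavities comparable in size to the spacing.

## Synthetic data: what it emulates, and what it does not

`generate_pedigree(f, c)` builds `f` nuclear families with two unaffected
parents and `c` affected children (the default study layout is 2 × 2 = 8
samples). `generate_variant_set` plants an exact number of qualifying
variants (children 1/1, parents 0/1) and actively corrupts every other
variant in at least one required sample, so planted counts are exact and
filter tests are deterministic, not statistical. Region classes are drawn
from a configurable mix (defaults 10 % exonic, 5 % each UTR, 40 % intronic,
40 % intergenic — intergenic-dominated as in real genomes, but compressed
so every class is exercised at small n). MAF is written as an INFO field;
the rare (MAF = 0) set preferentially covers the planted qualifying
variants, mirroring the design in which candidate recessive variants are
exactly the population-unobserved ones. Deleteriousness labels
(`benign` / `possibly_damaging` / `probably_damaging`) are attached to
exonic variants only, damaging with probability 0.6 by default.
`generate_network` grows a preferential-attachment background (edge scores
uniform on 150–850), plants an all-pairs module at weight 0.99 on the
latest-attached nodes (so the module is not confounded with background
hubs), and returns the lexicographically first half of the module as seeds,
holding out the rest as the recovery target.

Not emulated: sequencing reads, base quality, genotyping error, linkage/IBD
structure, population allele-frequency spectra, realistic network topology
beyond scale-freeness, or annotation noise. Passing tests therefore show
that the algorithms recover *cleanly planted* structure exactly and behave
correctly under their null models — they do not certify performance on real
cohorts, where the inheritance pattern can be broken by genotyping error
and the interaction network is both noisier and denser.

## Numerical choices and problem sizes

Convergence tolerance 1e-9 (L1), iteration cap 10 000; permutation ties at
1e-12 absolute tolerance; Bayes-factor integrals by adaptive quadrature on
the log-ratio scale. Test problem sizes were chosen to keep each property
informative at desk scale: kernel/oracle agreement on ≤ 50-node graphs at
1e-8, permutation-null uniformity with 1 000 permutations over ~200
candidate genes (KS test at the 1 % level), planted-module recovery on a
500-node graph, truth-table recovery over 20 generator seeds, exhaustive
hypergeometric enumeration up to 12-gene universes, and the cavity check at
0.25 Å spacing.

## Known limitations

* The recessive pattern requires *all* affected children homozygous and
  *all* their parents heterozygous across families; compound heterozygosity
  and X-linked inheritance are out of scope.
* HITS-with-priors has no mass-conservation interpretation as a random
  walk; its scores are comparable within a run only.
* The cavity extractor reports one cavity (the largest component); systems
  with several comparable voids need `largest_component=False` and custom
  post-processing.
* Empirical p-values are bounded below by `1/n_perm`; genes printed with
  p = 0 mean "never reached in `n_perm` permutations", not impossibility.
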