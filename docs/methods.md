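# Methods

## Scope and data model

The package implements the regulatory-network arm of a floral-induction
study: promoter motif scanning, expression-based edge refinement,
differential comparison of two condition-pair networks, and a k-mer survey
genome-size estimate. Genome assembly, annotation, TF/motif discovery,
phylogenetics and single-nucleus analyses are upstream concerns; motifs,
annotation and counts are *inputs* here.

Coordinates are GFF3 1-based inclusive on disk and 0-based half-open
internally; conversion happens exactly once, in the GFF3 reader. Only `gene`
feature rows are consumed, because promoters are defined from the annotated
gene start alone (no isoform-level TSS refinement).

## Promoter windows

"TSS −500 to +100" is realized as one half-open 600-bp interval: the 500
bases strictly upstream, then the TSS base plus 99 further downstream bases.
The source phrasing does not state inclusivity; this convention is
width-stable (unclipped windows are always `upstream + downstream` long, TSS
at index `upstream`) and strand-symmetric (extraction commutes with
reverse-complementing the genome). Windows are clipped at chromosome ends
and flagged; overlap with neighbouring genes is deliberately not trimmed, and
promoters shorter than a motif simply yield no hits.

## Motif scanning with exact p-values

Scores are pseudocounted log2-odds against a 0-order background
(default uniform; a promoter-composition estimator is provided):
`p̃(i,b) = (p(i,b) + γ·bg(b)) / (1+γ)` with γ = 0.1, the convention of the
standard occurrence scanners. Column scores are discretized to 1/1000 bit and
the exact null score distribution is built by position-wise convolution under
the background, so each window's p-value is the exact probability that a
random background word scores at least as high. Window scores use the same
discretized columns as the DP, hence DP tails equal brute-force enumeration
over all 4^w words to float precision (verified for w ≤ 6 in tests).

Both strands are scanned (the minus-strand model is the reverse-complemented
matrix; under a complement-symmetric background its null distribution is
identical, and the default background is uniform). Windows overlapping an N
are skipped, not background-scored. The 1e-5 cutoff is a raw per-test
threshold; no cross-position correction is applied, matching the original
filter. A practical floor worth noting: the smallest achievable p-value for a
width-w motif under a uniform background is 4^−w, so only motifs of width
≥ 9 can ever pass 1e-5; the synthetic motifs default to width 10.

## Differential expression

A deliberately minimal, self-contained NB test (an external caller's table
can be substituted via `de_table_from_frame`):

- **Normalization** — median-of-ratios: reference = per-gene geometric mean
  across samples (genes with any zero excluded from the reference, still
  normalized); size factor = median ratio to the reference.
- **Dispersion** — per-gene method of moments `α = (v − m)/m²` within each
  condition, pooled by degrees of freedom, floored at 1e-8 (Poisson fallback
  for negative estimates).
- **Test** — Wald statistic on `log2(m_b/m_a)` (means moderated by +0.5 to
  stay finite at zero), delta-method standard error
  `Var(log2 m̂) = (m + αm²)/(n m² ln²2)`, referred to a t distribution with
  `n_a + n_b − 2` df. The t reference counteracts the anti-conservativeness
  of plugging in a noisy dispersion at 4-vs-4; on a fully null NB benchmark
  (2,000 genes, dispersion 0.1) the raw p ≤ 0.05 rate is ≈ 0.05, and planted
  4-fold genes are recovered at ≈ 0.84–0.90 power at FDR ≤ 0.05.
- **DEG call** — |FC| ≥ 2 with BH FDR ≤ 0.05 (default); `criterion="raw_p"`
  reproduces the alternate raw-p reading. Genes with zero counts everywhere
  are reported untested.

Comparisons I-vs-C and F-vs-C feed the networks; criterion (ii) accepts a
DEG call in either (the union rule), and the comparison-specific rule is
available by passing a different DE-table selection to `deg_union`.

## Network assembly

Candidate edges come solely from motif occurrences in target promoters
(multiple hits collapse to one edge, the count kept as an attribute).
Spearman ρ uses average ranks on median-of-ratios-normalized counts over the
comparison's samples (default scope; all-samples scope available); constant
vectors give an undefined (dropped), never zero, correlation. Criterion (i)
defaults to |ρ| > 0.9 because negatively correlated (repression-like) edges
are an explicit part of the network model even though the published phrase is
">0.9"; `rho_mode="signed"` reproduces the literal reading. Self-edges are
excluded. Edges are sorted by (tf, target), so assembly is order-independent
and byte-deterministic.

## Differential comparison and enrichment

A node distinguishes the two networks if it is present in exactly one, or
present in both with a different signed directed neighbour set. Both
components (presence vs rewiring) are computed and reported; the published
figure's circled nodes have no formal definition, so the published P/odds
ratio are not reproduction targets. Enrichment of a family among
distinguishing nodes is an upper-tail hypergeometric test over a node
universe (default: union of both networks' nodes — the smallest defensible
choice; any explicit universe can be passed), with the 2×2 cross-product odds
ratio and a Haldane 0.5-per-cell correction when a cell is zero (flagged).
Testing several families applies BH across families.

## K-mer survey

Canonical k-mers (lexicographic min of word and reverse complement, so both
strands pool) are counted fully in memory with packed 2-bit integer codes —
adequate at desk scale; read pre-filtering is an upstream step. "Average
depth" in the size formula is ambiguous: the default takes the histogram
*peak* (modal multiplicity above the error trough, first local minimum over
the multiplicities actually present) because plain means are inflated by
error k-mers; `depth_mode="mean"` matches the literal formula. On 1 Mb /
30× error-free simulations the peak mode lands within ~1% of truth (the
integer mode quantizes depth), the mean mode within ~0.05%.

## Synthetic study design

The generator emulates the study conditions end to end, with ground truth
sufficient to score every stage (site recovery, DEG recovery, edge recovery
and sign, family rewiring). Defaults: 2 × 200 kb uniform-background
chromosomes; 300 genes (20 of them TFs) placed with ≥ 700 bp intergenic
clearance so promoters never clip or collide; width-10 motifs at 1.8
bits/column; 150 true edges (25% repressive); one exact-consensus site per
edge planted at a recorded promoter offset/strand; 3 conditions × 4
replicates.

Expression: each TF has a latent per-sample activity = condition mean
(0 or ±2 log2 units, the planted 4-fold effect) + N(0, 0.7) jitter; targets
track their TF's activity with weight 2.5 and the planted sign; counts are NB
with dispersion 0.02 around mean 1000 (clonal single-plantlet replicates are
tight; the dispersion-dominated CV is ≈ 14%). The differential family
(6 TFs) shares one latent factor active only in F; its 12 shared pool targets
are decoupled in I samples, so family edges exist in the C–F program and
vanish from C–I — the positive control for the enrichment stage. These
constants were fixed once, by simulation during design, so that the planted
structure is *coherent*: planted pairs genuinely clear the 0.9 rank-
correlation threshold at n = 8 while unrelated pairs do not (the threshold is
attainable and violable), planted effects are detectable at 4-vs-4, and
family rewiring dominates the distinguishing set. Four independent RNG
streams (genome, sites, expression, reads) derive from the master seed, so
artifacts are byte-reproducible and stages can change independently.

What the generator does **not** emulate: realistic genome composition
(repeats, GC structure, isoforms), shared-factor co-regulation outside the
planted family, batch effects, library-size heterogeneity beyond size
factors, and sequencing error models beyond uniform substitution. Passing
tests therefore demonstrate correctness of the algorithms under the planted
model, not performance on real *W. australiana* data, whose effect sizes the
source does not quantify.

## Numerical choices and degenerate inputs

- Motif rows must sum to 1 ± 1e-3 and are renormalized (published matrices
  are rounded).
- Score discretization 1/1000 bit: standard accuracy/speed trade-off; p-value
  queries clamp to [min, max] achievable scores.
- Zero pseudocount with a zero matrix or background entry is an error
  (undefined log-odds), not a silent −inf.
- BH is computed over tested genes only; NaN p-values propagate.
- Empty networks, empty hit tables, header-only edge files and empty draws
  (n = 0 ⇒ p = 1) are all defined, tested paths.
- Problem sizes used in tests and the acceptance script (300-gene study,
  2,000-gene DE benchmark, 1 Mb survey genome) are the package's desk-scale
  defaults chosen to exercise every stage; all scale linearly if enlarged.

## Known limitations

- The NB test has no dispersion shrinkage/moderation, covariates or outlier
  handling; it is a calibrated minimal reference implementation, and any
  external DE table can be substituted.
- Exact p-values assume a 0-order background; higher-order and gapped/variable
  -length motifs are out of scope.
- The k-mer counter is in-memory; billions of k-mers need a disk-based tool.
- Spearman at n = 8 is coarse (the smallest nonzero distance from 1 is
  ~0.024), so the 0.9 threshold behaves as a high-pass step; this mirrors the
  original design rather than improving on it.
- Heterozygosity estimation and GenomeScope-style mixture fitting are not
  implemented (no method stated upstream; out of scope).
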