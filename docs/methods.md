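# Methods

This package implements a multi-region, multi-omics differential analysis
stack — bulk RNA differential expression, differential histone-acetylation
peak calling, cross-region module discovery, set enrichment, cross-modality
integration and a single-cell stage — together with a synthetic-data
generator that plants recorded ground truth with the statistical structure
the analysis assumes. This note documents the models, the defaults and why
they were chosen, the numerical decisions, and what a green test does and
does not establish.

## Synthetic data (`regionomics.simdata`)

### Bulk counts

Counts for gene *g*, sample *s* are negative binomial with mean
`sf_s * base_g * 2^(effect_{g,r})` (effect applied in treated samples only)
and variance `mu + alpha_g * mu^2`:

- `base_g ~ lognormal(4.0, 1.5)` — median ≈ 55 counts, heavy right tail,
  typical of bulk RNA-seq at ~20–30 M reads;
- `alpha_g ~ Gamma(shape 2, mean 0.1)` — the common bulk overdispersion
  range; a degenerate gamma (`shape → inf`) pins dispersion exactly for
  power studies;
- size factors `sf_s ~ lognormal(0, 0.2)` so normalization is non-trivial;
- effects are planted as modules: disjoint gene sets sharing a per-region
  log2 fold-change. The default design (27 regions × 2 conditions × 4
  replicates) mirrors a whole-brain region-panel study.

### ChIP peaks

One promoter peak per gene (centre within ±1 kb of its TSS on a synthetic
50-kb-spaced single chromosome) plus distal decoy peaks ≥ 10 kb from any
TSS, which makes promoter assignment unambiguous in tests. Promoter-peak
effects are `rho * e + sqrt(1 - rho^2) * sigma_r * z` for genes with a
planted expression effect `e` (`sigma_r` = the spread of planted effects in
that region), so the planted peak-vs-gene correlation equals `rho`; decoys
and null genes carry no effect. Peak counts use the same NB machinery with
2 replicates per condition and defaults `base ~ lognormal(6.5, 1.0)`,
`alpha ~ Gamma(2, mean 0.01)`: the design this emulates sequences pooled
replicates (tens of animals per pool) deeply, so per-peak counts are in the
hundreds and replicate concordance is near-technical. With only 2
replicates per condition the moderated-t reference has 4 degrees of
freedom; shallow or noisy peak counts would make region-level discovery
essentially impossible, which is not how such designs behave in practice.

### Single cells

Cells are multinomial draws over a type-specific expression profile:
baseline gene weights `lognormal(0, 1)`, the type's marker block elevated
8-fold, mitochondrial genes fixed at a weight giving ~3% mito fraction.
Per-cell depth is Poisson–lognormal around 2,000 counts (droplet-like
sparsity at desk scale). Replicate structure: per-replicate Dirichlet
noise on type proportions (concentration 200) and per-replicate lognormal
expression noise (sd 0.15) independent between conditions, so pseudo-bulk
units genuinely vary. Planted perturbations (all treated-only, all
recorded in the truth table):

- **proportion shift** — planted on the proportion scale: the shifted
  type's expected share becomes `fold × base` and only the other types are
  renormalized, so the realized ratio matches the planted fold;
- **module / regulon shifts** — the gene set (or TF target set) is
  multiplied by `2^lfc` in the target type's profile;
- **ligand–receptor shift** — the ligand gene is multiplied by `2^lfc` in
  the sender type.

Because profiles are probability vectors, any planted elevation slightly
deflates all other genes of that type (compositional renormalization).
This is intentional — droplet counts are compositional — but it means
"null" genes in a perturbed type are weakly non-null, and unshifted types
lose a little mass under a proportion shift.

What the generator does **not** model: pooling variance within a replicate
(real replicates are pools of animals; the generator draws replicates
directly), batch effects beyond size factors, doublets, ambient RNA,
read-level or fragment-level signal. A green planted-recovery test
establishes that the estimator recovers effects under the stated NB /
multinomial world, not under these extra noise sources.

## Differential calling (`regionomics.diffcount`)

One engine serves genes and peaks. Per region:

1. **Normalization** — median-of-ratios size factors over features with no
   zero count, rescaled to geometric mean 1. Note a deliberate wrinkle:
   with the geometric-mean-1 convention, scaling one sample's library by
   `c` rescales *all* normalized counts by `c^(1/n)`, so log2FC computed
   with an additive pseudocount is invariant only up to a `c^(1/n)`-order
   term on weakly expressed features. The property test asserts exact
   factor-ratio scaling and log2FC stability at 1e-3 on well-expressed
   features.
2. **Dispersion** — method-of-moments on normalized counts (df-weighted
   within-condition variances), clipped at 0, then shrunk 50/50 toward a
   parametric trend `alpha(mu) = a0 + a1/mu` fitted by least squares with
   one MAD-based trimming pass and non-negative coefficients.
3. **Test** — Wald statistic of `log2FC != 0` on pseudocounted (0.5)
   normalized condition means, with the delta-method NB variance
   `Var(mean_c) = (mu_c * sum(1/sf_i) + alpha * mu_c^2 * n_c) / n_c^2`.
   The statistic is referred to a **moderated t with df = 2·(n1+n2−2)**:
   the 50/50 shrink is an empirical-Bayes prior whose precision equals the
   per-feature estimate, which in the limma convention contributes prior
   degrees of freedom equal to the residual degrees of freedom. With a
   plain normal reference the extreme tail is strongly anticonservative at
   n = 4 per group (most global-null datasets produce a false discovery at
   q ≤ 0.1); the moderated t restores finite-sample FDR control at a real
   cost in power. At the stated power-study world (|log2FC| = 1, mean 200,
   dispersion 0.1, n = 4, 200 planted among 2,000 features) even an oracle
   z-test knowing the true dispersion has mean sensitivity ≈ 0.61, so the
   calibrated engine's ≈ 0.28 is the honest price of tail calibration, not
   an implementation defect.
4. **Thresholds** — BH per region and per modality; status `up` iff
   `log2FC ≥ log2(1.25)` and `q ≤ 0.1` (`down` symmetric). All-zero
   features are reported `ns` with absent p/q. Ties are deterministic
   because input feature order is preserved.

## Modules and sharing (`regionomics.modulemap`)

The fold-change matrix holds features differential in ≥ 1 region; untested
entries enter as 0 ("no evidence of change") with a companion mask, and
the masked count per module is reported. Clustering is k-means
(k-means++, best of 25 restarts, seeded) on **raw** log2FC profiles — the
sign/magnitude pattern across regions is the biology; z-scoring is an
option (`scale_rows=True`) but would conflate a globally-up module with a
region-specific one. `k` defaults to 8 for both genes and peaks and is a
config knob. Sharing summaries count per-direction regions per feature and
report the fraction of union features differential in exactly 1 and in ≥ 3
regions.

## Enrichment (`regionomics.enrich`)

- **ORA** — exact hypergeometric upper tail, fold-enrichment
  `(k/n)/(K/N)`, BH across the collection. The universe is the features
  *tested* in that region, not the genome — detection bias otherwise
  inflates enrichment.
- **GSEA** — weighted (w = 1) KS running sum; hit increments proportional
  to `|score|^w` normalized over the set, miss decrements `1/(N−K)`; ES is
  the extreme deviation with ties broken toward the positive side. The
  null is **gene permutation** (seeded), not phenotype permutation: with
  4 replicates per condition there are too few label permutations for a
  usable phenotype null. NES divides ES by the mean |ES| of same-sign
  permutation nulls; the p-value is the one-sided permutation tail with
  the +1 correction.
- **Genomic-region binomial** — regulatory domains are basal (TSS ± 5 kb)
  plus extension up to 100 kb or the nearest neighbouring basal domain;
  peaks count by midpoint membership in the union of a set's domains
  (unambiguous for border-straddling peaks); p is the exact binomial upper
  tail with p0 = the union's genome-coverage fraction.

## Integration (`regionomics.integrate`)

- **Promoter assignment** — nearest TSS within ± 2 kb of the peak
  midpoint, strand-ignored (acetylation flanks promoters on both sides);
  distance ties break to the lexicographically smaller gene id.
- **Concordance** — Spearman rho (average ranks) between DEG log2FC and
  their assigned differential promoter-peak log2FC; exact permutation p
  for ≤ 10 pairs (vectorised enumeration), t-approximation above.
- **Composite region ranking** — counts ranked descending with average
  ties; score = `ln(rank_RNA) + ln(rank_ChIP)`, ascending; depends only on
  ranks, hence invariant to monotone transforms of the counts.
- **RRHO** — both lists sorted most-upregulated first by signed score
  (default `−log10(p)·sign(log2FC)`, falling back to signed log2FC for
  untested features); cell (i, j) stores `−log10` of the hypergeometric
  upper-tail p of the top-i·s vs top-j·s overlap, with a separate sign
  grid marking depletion (overlap below expectation). Default step
  `max(1, N // 100)` caps the grid at 100 × 100. No multiplicity
  correction — the map is a display statistic.

## Single-cell stage (`regionomics.scpipe`)

- **QC/normalization** — cells need ≥ 500 detected genes (demo configs use
  lower values at their smaller gene universes) and mito fraction ≤ 0.20;
  genes must appear in ≥ 3 surviving cells; normalized value
  `log(1 + 1e4·count/total)`. QC metrics are computed once from the raw
  library and stored in `obs`, so the operation is idempotent by
  construction and normalization is invariant to gene filtering.
- **Cell typing** — step 1: Spearman correlation of each cell's
  marker-gene profile against reference centroids (binary marker centroids
  or mean profiles of a labelled reference), argmax if ≥ 0.2 else
  `ambiguous`; step 2: k-means (k = number of types) on the top-20 PCs,
  with cells whose supervised label disagrees with their cluster's
  majority flagged `low_confidence`.
- **Proportion tests** — per-replicate proportions, two-sided rank-sum.
  Rank-sum tests use the **exact conditional distribution** (enumeration
  over the observed, possibly tied, ranks) whenever the two groups hold
  ≤ 12 observations, and the tie-corrected normal approximation above
  that. Under a proportion shift the other types are genuinely (weakly)
  depleted by renormalization, so nominal-level flags on unshifted types
  are expected behaviour, not false positives in the strict sense.
- **Pseudo-bulk DE** — units are mean normalized expression per
  (condition, replicate) over that type's cells (≥ 10 cells per unit, ≥ 2
  units per condition); per-gene Welch t-test across units, log2FC from
  unit means with pseudocount 0.1, BH per type, thresholds
  `|log2FC| ≥ log2(1.25)`, `q ≤ 0.2`. Mean aggregation + t-test (rather
  than summed counts + NB) matches the "averaged pseudo-bulk profile"
  convention.
- **Module scores** — per cell, mean normalized expression of the set
  minus the mean over control genes drawn from the same average-expression
  bin (25 equal-width bins anchored at 0; 100 controls per set gene; each
  gene's draw seeded from (seed, crc32(gene))), making scores reproducible
  and invariant to genes that enter neither the set nor a set gene's bin.
  The per-type comparison is a cell-level rank-sum: cells within a
  replicate share replicate noise, so this test is anticonservative when
  replicate-level expression variation is present — which is exactly why
  pseudo-bulk DE, not the cell-level score test, is the primary DE
  instrument here.
- **Regulon activity** — AUCell-style: genes ranked per cell by normalized
  expression (ties broken deterministically by gene order); activity is
  the area under the recovery curve of regulon genes within the top 5% of
  ranks, normalized to [0, 1] by the maximal achievable area; per-type
  rank-sum on activities, BH across regulons within type, significance at
  q < 0.1. Regulon *discovery* is out of scope; regulons are inputs.
- **Ligand–receptor edges** — specificity of a ligand for a sender type is
  its **linear-scale** mean normalized expression share across types
  (0/0 → 0); log-scale means would compress a true doubling into the
  noise. Edge weight = ligand specificity × receptor specificity per
  condition; edges require ≥ 10% detection of ligand (sender) and receptor
  (receiver) in ≥ 1 condition; edges sorted by |Δweight|. Specificities
  sum to 1 over types for every expressed gene by construction.

## Pipeline (`regionomics.pipeline`, CLI `regionomics`)

YAML config over defaults; every stage reads only files written by
earlier stages, so stage subsets can be re-run against an existing output
directory; a failing stage writes the manifest with its failure recorded
and halts (exit 3 from the CLI, exit 2 for validation errors). Outputs
are TSV with stable column order and 6-significant-digit floats; the JSON
manifest records config hash, seed, stage timings and SHA-256 hashes of
every output, so end-to-end determinism is checkable by comparing
manifests. The packaged demo config (8 regions, 1,000 genes, 4+4 bulk
replicates; 2 single-cell regions, 6 types, 5+5 replicates) runs in a few
seconds and plants its strongest budget in region R01 ("raphe-like": most
effects in both modalities) and one effect of every single-cell kind in
the first single-cell region.

## Known limitations

- Power at the bulk design's scale is materially limited by n = 4 per
  group plus the moderated-t reference; see the dispersion/test section.
- The per-region trend fit sees only that region's samples; a whole-design
  dispersion fit (as practitioners do with large factorial designs) would
  be more powerful but is outside the per-region engine contract.
- Cell-level rank-sum tests (module scores, regulon activity) treat cells
  as independent; with replicate-level noise they are anticonservative.
- The exact Spearman permutation p enumerates up to 10! orderings;
  vectorised but still the slowest path (seconds), used only for ≤ 10
  pairs.
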