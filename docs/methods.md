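# Methods notes

This note records the model assumptions, parameter choices, numerical
conventions, and known limitations of `orthowindow`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The comparability model

The method assumes that for a pair of 1:1 orthologs measured under matched
conditions, per-base sequencing depth along the gene is (a) highly correlated
between replicate libraries of the same species and (b) approximately
linearly related between species once both profiles are expressed over the
*same* alignable sequence. Departures from (b) localize either to whole genes
(annotation or assembly problems, paralogous read attraction) or to specific
windows (one-species coverage distortions). The screen removes both: genes by
the correlation/sign-test decision, windows by robust-regression outliers.

The sign-test rescue encodes the one biological exception: a genuinely
differentially expressed gene can have low interspecies profile correlation
simply because one species' profile is near noise level, yet its coverage is
then *consistently* higher in the other species. Consistency in direction,
not shape, is the rescue criterion, and rescued genes are exempted from
window-level outlier removal (their fit is dominated by the expression shift
itself).

## Windowing and coordinate conventions

- Windows are 25 **alignment columns** (not ungapped bases of either
  species). Measuring in columns keeps the two species symmetric; the
  alternative (ungapped bp of one species) would make window identity depend
  on which species is listed first. Terminal partial windows are dropped so
  every identity fraction has the same denominator.
- A column is a gap column if either row holds `-` (`.` is normalized on
  input); "fewer than 3 bp gaps" is applied as ≤ 2 gap columns, strictly.
  Identity is matches over the full window length, so gap columns penalize
  identity; `N` matches nothing, comparison is case-insensitive. Both
  boundaries are strict: identity exactly 0.70 or exactly 3 gap columns
  fail. An alternative convention (identity over non-gap columns only) is
  noted but not implemented; with ≤ 2 gap columns the two differ by at most
  ~8 % of the denominator.
- All in-memory coordinates are 0-based half-open; GTF I/O converts to
  1-based inclusive. Minus-strand genes map transcript position 0 to the
  highest genomic coordinate of the last exon (reverse-complement walk).
  The transcript→genome map splits intervals at exon junctions; the inverse
  map is exact, and a property test checks the round trip on both strands.
- Genes retaining fewer than `min_windows = 4` windows are excluded
  outright: a correlation over fewer than 4 points carries no information.
  This threshold is a package choice (configurable), not part of the
  published filter chain.

## Built-in aligner

Precomputed alignments (aligned FASTA, 2 records) are the recommended input;
the built-in global aligner exists for fixtures and small inputs. It is
Biopython's `PairwiseAligner` in global mode with affine gaps (defaults
match = 2, mismatch = −3, gap open = −5, gap extend = −2; a length-L gap run
costs open + (L−1)·extend, end gaps included) and a substitution matrix in
which `N` mismatches everything. Co-optimal alignments are resolved by the
aligner's fixed enumeration order, so output is deterministic; tests compare
its scores against an independent exhaustive recursion oracle.

## Coverage normalization

Each sample's window depths are scaled by 10⁶ / (total depth mass of the
track) before replicate averaging. Pearson r is scale-invariant, so this
choice only matters for the sign test, which needs a defined cross-library
comparison; per-million mass scaling is the simplest such convention. Mean
per-base depth (not read count) is the window statistic because it is
robust to windows split across exon junctions. Replicates are combined by
arithmetic mean.

A consequence worth knowing: per-million scaling inherits composition bias.
If strongly up-regulated genes carry more depth mass in one species, every
gene's normalized profile shifts slightly against that species, and for
genes with many windows the sign test can reach significance on a small
consistent shift. With a symmetric fold-change distribution and hundreds of
genes the effect is negligible, but on very small gene sets the sign-test
rescue becomes anti-conservative for discordant genes. The parameter-recovery
tests measure pure populations (all-concordant, all-discordant) for exactly
this reason; the mixed-population acceptance run measures overall accuracy.

## Concordance decisions

Per gene, with replicate-averaged profiles x (species 2) and y (species 1):

- Pearson r on the raw normalized profiles; r undefined (zero variance)
  is treated like low r.
- Sign test: windows with exactly equal values are dropped (standard sign
  test practice); two-sided p is the doubled smaller exact binomial tail,
  capped at 1. The rescue threshold is p < 0.001 per gene, deliberately not
  FDR-corrected — it mirrors a fixed per-gene screen, not an inference.
- Robust fit: `statsmodels` RLM, Huber loss with tuning constant 1.345,
  IRLS to relative tolerance 1e−8 or 50 iterations. Residual scale is
  1.4826 × MAD about the median residual. Windows with |scaled residual| >
  2.5 (strict) are outliers; 2.5 is a conventional cutoff, configurable.
  If the MAD degenerates to zero (a majority of windows fit exactly),
  residuals at numerical-noise level are not outliers and any genuine
  deviation is; an exact fit therefore flags nothing spurious while a
  half-exact fit with gross points still flags them.
- Species 2 (second column of the pair list) is the regression x by
  convention; scale-invariance of the decision is tested rather than
  assumed. Outlier removal does not re-run the correlation screen.
- A retained gene must still hold ≥ `min_windows` windows after outlier
  removal, else it is excluded as degenerate.

## Quantification and normalization

- Union-mode counting: a fragment (pre-merged mate pair, BED interval)
  is assigned iff it overlaps ≥ 1 bp of retained windows of exactly one
  gene; multi-gene overlap is ambiguous and discarded; strandedness is off
  (fixture fragments carry no strand). Assigned + ambiguous + unassigned
  always equals the fragment total per sample.
- TMM: reference defaults to the sample whose upper-quartile count rate is
  closest to the mean; per-gene M and A values over genes nonzero in both
  samples are rank-trimmed (30 % per side on M, 5 % per side on A) and
  averaged with inverse delta-method-variance weights. Factors are
  reference-relative (the reference's factor is exactly 1); no cross-sample
  geometric recentering is applied. No gene-length term enters because the
  paired comparable lengths are near-equal by construction.
- CPM uses effective library size (column sum × TMM factor); FPKM divides
  CPM by the species' own comparable length in kb and is intended for
  display — cross-species DE should work from counts/CPM.
- Fold changes use a 0.5-CPM pseudocount. Negative-binomial DE testing is
  intentionally out of scope; adjusted p-values are accepted from an
  external DE engine and only thresholded here (adj p < 0.05,
  |log2FC| > 1, both strict).
- Welch's t-test (unequal variances, Welch–Satterthwaite df, two-sided) is
  provided for validating individual genes against an orthogonal assay;
  the degenerate zero-variance-both-groups case raises an error when means
  differ and returns p = 1 when they agree.

## Synthetic data

The generator emulates what the method assumes about real data, not the
sequencing process itself:

- Sequences: a random ancestor (500–3000 bp) evolves independently into two
  lineages with per-site substitution rate 0.10 (rodent-scale transcript
  divergence), indel initiation rate 0.005 per site with geometric(0.5)
  lengths, and no transition/transversion asymmetry. The true column-level
  alignment is recorded, so alignment error is excluded by design.
- Gene models: 1–6 exons of ≥ 30 bp, introns 100–2000 bp, random strand,
  each gene on its own chromosome (no overlap bookkeeping, no shared
  fragments between genes except through the annotation under test).
- Coverage: each gene has a latent lognormal(0, 1) window-weight profile.
  Concordant genes share it across species, scaled by 2^log2FC with
  log2FC ∈ {−2, 0, +2}; discordant genes (a third of genes by default) draw
  independent profiles. Replicate depth = 50 × weight × lognormal(0, 0.2)
  noise. A 5 % fraction of windows in concordant genes gets a 5× depth
  distortion in one species only — the planted outliers for the robust
  screen. Bias is planted only in concordant genes so the discordant
  exclusion statistic is unconfounded.
- Fragments: per-gene abundance lognormal around 100 fragments (σ_log 0.5),
  species scaled by 2^log2FC, replicate counts Poisson, 100-bp fragments
  placed uniformly in comparable bases and clipped to their segment.
- Determinism: every gene draws from `default_rng([seed, gene_index,
  stream])`, so outputs are byte-identical for a fixed config and stable
  per gene when `n_genes` changes; floats serialize at 6 significant
  digits.

What the simulator does **not** model — and what passing tests therefore do
not demonstrate about real data: alignment error (true alignments are used),
read-level sequencing error, GC/positional coverage bias along transcripts,
spliced-read edge effects, multi-isoform genes, paralogous multi-mapping,
and biological overdispersion beyond Poisson counting noise.

## Problem sizes

The acceptance run simulates 300 genes (about a third discordant) with 3
replicate libraries per species — large enough for stable population
statistics while keeping the pipeline's end-to-end run under a minute.
Property suites use 200-gene pure populations and 1000-interval coordinate
sweeps. These sizes are package choices for routine verification;
all stages stream per gene and scale linearly in gene count.

## Known limitations

- One designated transcript per gene; isoform-level comparability is out of
  scope.
- The sign-test rescue inherits composition bias from per-million coverage
  scaling (see above).
- FPKM over comparable regions understates whole-transcript abundance by
  construction; it is comparable across species, not against conventional
  FPKM of the full gene model.
- TMM assumes most genes are not differentially expressed between the
  compared samples; with strongly asymmetric fold-change distributions the
  factors absorb real signal (the double trim gives considerable, not
  unlimited, robustness).
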