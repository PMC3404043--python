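# Methods

## The DE procedure and its assumptions

The pipeline targets a design with **no biological replicates**: one
pooled-oocyte library per condition per disease model. With n = 1 per
group no variance can be estimated per gene, so calling is threshold-based
on the fold change rather than p-value-based. The procedure conditions on
detectability (the >10-summed-reads filter), splits genes into expression
strata, and demands a larger fold change from weakly expressed genes,
where the sampling noise of small counts inflates apparent ratios. All
threshold comparisons are strict inequalities ("more than", "bigger
than"): a gene at log2FC exactly 0.8 (high stratum) or exactly 2.0 (low
stratum) is *unchanged*.

Several details of the procedure are underdetermined by its verbal
description; the package resolves them as follows, each behind a
configurable parameter:

- **Filter scope.** "Reads count more than 10" is applied to the *sum* of
  raw counts over the model's control + diabetic libraries — the least
  arbitrary single number per gene; a per-library minimum would be the
  natural alternative (`FilterParams.min_reads` applies to the sum).
- **Stratification base.** The grand mean is computed *after* filtering,
  over the per-gene means of the model's two normalised libraries; each
  model is stratified independently. "All detected genes" most plausibly
  means the post-filter set, since undetected genes contribute almost
  nothing to a mean over 16k genes either way.
- **Normalisation.** Default CPM. With one library per condition and
  similar depths, CPM shifts every log2FC by the same constant
  `log2(depth_ctrl/depth_diab)` relative to raw counts, so the choice only
  matters under unequal depth; `normalization="none"` reproduces the
  literal raw-count procedure.
- **Pseudocount.** ε = 0.5 added to both numerator and denominator keeps
  fold changes finite for genes that are zero in one library while
  preserving antisymmetry under condition swap.

## Enrichment

One-sided (upper-tail) hypergeometric probabilities, equivalent to the
one-sided Fisher exact test — "enrichment" is an over-representation
question, so the upper tail is the default; a two-sided variant exists for
completeness. The universe is the detection-filtered gene set (union of
both models' filtered sets when testing the shared list): the test must
condition on which genes could have been called at all. Raw p-values are
reported by default — the procedure is a ranked screen, not a
significance filter — with Benjamini–Hochberg q-values behind a flag
(`adjust_pvalues(..., "bh")`). GO-slim collapsing takes an explicit
term → slim-term table and unions member sets; no ontology-graph
propagation is attempted (supplying the mapping keeps the package free of
OBO parsing and of database-version drift).

The scipy hypergeometric survival function provides the tail probability;
the test suite verifies it against an independent exact integer
enumeration (binomial-coefficient sums) over every margin with N ≤ 50 at
1e-12, including the worked example N=10, K=5, n=4, k=4 → p = 5/210.

## The synthetic-data generator

`SyntheticSpec` defaults define the emulated study:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 16,457 | detected genes |
| `library_size` | 2×10⁶ | expected reads per library |
| `baseline_shape` | (0.0, 2.42) | log-normal (μ, σ) of per-gene mean expression |
| `dispersion` | 0.05 | NB dispersion φ; Var = μ + φμ² (0 ⇒ Poisson) |
| `frac_de_up` / `frac_de_down` | 0.073 / 0.040 | planted DE fractions per model |
| `lfc_high` / `lfc_low` | 2.0 / 3.0 | planted \|log2FC\| by generation-time stratum |
| `frac_shared` | 0.45 | fraction of each model's DE genes common to both |
| `n_replicates` | 1 | libraries per condition (1 matches the no-replicate design) |

The log-normal σ = 2.42 was calibrated once, by simulation, so that the
number of genes with more than 10 summed reads per model lands near 8,792
of 16,457 (the emulated detection scale); with planted DE the realised
count sits a few percent above the null value, still within ±10%. The DE
fractions mirror the scale of per-model up/down lists of roughly a
thousand and several hundred genes; `frac_shared` = 0.45 puts the
concordantly changed sets in the several-hundred range. Planted DE is
multiplicative on the diabetic library's mean, matching the fold-change
read-out. Identical specs (including the seed) give bit-identical output.

What the generator does **not** emulate: mapping artifacts, amplification
bias from the two-round PCR library construction, gene-length effects,
correlated gene programs (genes are independent given their means), or
any real ontology structure (terms are random gene sets with an optional
planted enrichment). Passing tests therefore demonstrate the pipeline's
internal correctness and its behaviour under a realistic count
distribution — not agreement with any particular real dataset.

The annotation generator plants enrichment by weighted sampling: member
genes of an enriched term are drawn with odds `enrichment_odds` : 1 in
favour of true-DE genes (∞ ⇒ the term contains only true-DE genes). The
qPCR generator returns the true log2FC plus N(0, `noise_sd`) per gene,
modelling a ΔΔCt-style relative quantification with 0.25 log2 units of
default noise.

## End-to-end driver choices

The qPCR validation panel in the pipeline driver is the top
`qpcr_panel_size` (10) called genes per model ranked by |log2FC| **among
high-stratum calls with both condition means ≥ 5 CPM**. The expression
floor matters: without it, one-sided dropouts (zero in one library, a
handful of reads in the other) dominate the |log2FC| ranking with
apparent fold changes that reflect sampling noise rather than signal, and
a re-measurement panel built from them shows no correlation. Restricting
to well-measured strong hits mirrors how validation panels are chosen in
practice and yields sequencing-vs-qPCR r ≈ 0.95–0.99 across seeds.

Cross-model classes: a gene up in one model and down in the other is
reported as **discordant**, a class of its own — it is neither shared nor
cleanly model-specific, and folding it silently into either would bias
the shared counts. Genes filtered out of one model count as unchanged
there, so a gene DE in A and undetected in B is `up-A-only`/`down-A-only`.

## Numerical and degenerate-input conventions

- Enrichment ties are broken by term accession for a deterministic order;
  p-values are clipped into (0, 1].
- Terms with no universe genes after intersection are omitted, not scored.
- Empty filtered tables, empty DE lists and empty annotations flow through
  every stage as empty results with warnings, never exceptions; true
  contract violations (DE genes outside the universe, zero-total library
  under CPM, fewer than 3 concordance pairs, zero-variance vectors) raise.
- Gene identifiers are opaque case-sensitive strings; no alias resolution.

## Problem sizes in the test suite

The acceptance-style checks run at the defaults' full scale (16,457
genes) where the property concerns scale itself (filter calibration, null
false-positive rates) and at 4,000 genes / 6×10⁵ reads for the
planted-recovery and enrichment-rank replicates, which repeat 100 times;
these sizes give stable statistics while keeping the whole suite in the
tens of seconds on a single CPU.

## Known limitations

- Without replicates the false-positive calibration is purely synthetic;
  on real data the thresholds inherit whatever biological variance exists
  between pools.
- The stratification threshold depends on the post-filter mean, so adding
  or removing genes from the table can move genes between strata.
- GO-slim collapsing with explicit tables cannot discover ancestors not
  present in the supplied mapping.
- The two-sided Fisher option uses the point-probability method of
  `scipy.stats.fisher_exact`, which need not equal doubling the smaller
  tail.
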