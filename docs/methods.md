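# Methods

## Overview

`trlmap` operationalizes a simple idea: a T cell in a single-cell atlas is a
putative tumor-reactive lymphocyte (TRL) if its TCRβ clonotype also appears in
a reactivity-sorted repertoire (4-1BB⁺ after tumor co-culture, or
antigen-dextramer sorted). The pipeline runs: PDX host/graft splitting →
quality control → clonotype construction and matching → per-cluster
enrichment statistics → pseudo-bulk aggregation. Upstream steps (alignment,
contig assembly, ambient-RNA removal, clustering, per-cell doublet scoring)
are treated as inputs.

## Clonotype model

A clonotype is the triple (CDR3β amino-acid sequence, Vβ gene, Jβ gene).
This is deliberately β-only: bulk TCR profiling does not pair α and β chains,
so the triple is the finest identity observable in *all* assays being
matched. Consequences and conventions:

- IMGT allele suffixes (`*01`) are stripped before matching; bulk and
  single-cell profilers report different allele resolution.
- A barcode with several productive TRB contigs takes its key from the
  highest-UMI TRB; exact ties break to the lexicographically smallest CDR3.
  This mirrors the consensus convention of standard V(D)J callers.
- Cells with more than one productive TRA are flagged (`multi_alpha`) and
  excluded only from specificity-group preparation (external tools do not
  support them), never from matching — the β chain is unambiguous.
- Presence in a bulk table is binary: any positive read count. No UMI
  deduplication is attempted on bulk data.

## Enrichment statistics

For cluster *k*: *x* = reactive cells in *k*, *n* = all reactive cells,
*p₀ₖ* = fraction of TIL-matching cells in *k*. The two-sided exact binomial
p-value uses the minimum-likelihood rule: sum of Bin(*n*, *p₀ₖ*)
probabilities over outcomes whose point mass is ≤ pmf(*x*) × (1 + 10⁻⁷).
The relative tie tolerance matches the reference implementations and absorbs
floating-point asymmetry in exact ties. Implementation is full enumeration of
the pmf via a cached log-factorial table; this is exact and costs O(*n*),
which is negligible at repertoire scale. Bonferroni adjustment multiplies by
the number of clusters tested (every cluster with clonotyped cells is
tested). Degenerate backgrounds (*p₀ₖ* = 0 with *x* > 0) are still tested and
flagged `degenerate_background` rather than dropped. The per-cluster
difference Δ = freq(matching) − freq(non-matching) sums to zero over
clusters by construction.

Fisher's exact test (used by QC) follows the same minimum-likelihood rule on
the hypergeometric distribution with fixed margins; the reported odds ratio
is the sample OR (a·d)/(b·c), with ∞ when b·c = 0 and a·d > 0 and NaN when
both products vanish (a degenerate margin, p = 1).

Both tests are verified against exhaustive exact rational-arithmetic
enumeration (every binomial case with n ≤ 60 on a 0.05 p₀ grid; every 2×2
table with total ≤ 60) to within 10⁻¹², and cross-checked against
independent reference implementations.

## Quality control

Stages, in order:

1. **Global thresholds.** Two shipped profiles. `biopsy` phrases *retention*
   criteria, so comparisons are strict (kept iff genes > 200, UMIs > 500,
   ribo % < 40, top-100 % < 80; a pre-filter drops cells with <200 reads).
   `um1` phrases *removal* criteria strictly, so retention is inclusive
   (kept iff genes ∈ [400, 6500], UMIs ∈ [500, 25000], mito % ≤ 20,
   ribo % ≤ 15). A `QCProfile` carries an `inclusive` flag to encode either
   phrasing; thresholds on metrics missing from the table are configuration
   errors. The adaptive mixture-model filtering some workflows add after
   hard thresholds is out of scope here; the `um1` hard-threshold profile is
   the supported alternative.
2. **Lineage-conflict doublets.** "Expressed" means raw count > 0 (no
   cutoff is imposed beyond detection). Rules are ordered pairs of marker
   sets; the shipped set encodes T-cell identity (CD3D/CD4/CD8A/CD8B or an
   assembled TCR) vs melanocytic (MLANA/PMEL/TYR) and erythroid
   (HBA1/HBA2/HBB) programs, assembled TCR vs CD14/CD19/MS4A1/JCHAIN, and
   melanocytic vs monocyte/B/plasma/NK markers. Missing symbols are logged
   and the rule evaluated on the remainder; flagging is monotone in
   expression.
3. **Doublet clusters.** Per cluster, the 2×2 table
   (doublet, singlet) × (in-cluster, out-of-cluster) is Fisher-tested, BH
   adjusted across clusters. The table is oriented so OR > 1 means doublet
   over-representation, and the removal criterion is OR > 1 ∧ q < 0.05;
   a `fisher_or_direction="under"` switch restores the literal OR < 1
   reading for comparability (it emits a warning, since removing
   doublet-*depleted* clusters is almost certainly not intended).
   Additional nomination criteria: cluster doublet percentage ≥ the 95th
   percentile of cluster doublet percentages (inclusive, so the maximum is
   always nominated), and cluster **median** UMI strictly above the 95th
   percentile of cluster medians (the summary statistic is configurable; a
   deterministic criterion replaces visual inspection for reproducibility).
4. **Low-RNA rescue.** Candidates by markers (erythrocytes: any of
   HBA1/HBA2/HBB; plasma cells: JCHAIN > 0 with IL3RA = LILRA4 = 0 to
   exclude plasmacytoid dendritic cells). Candidate–candidate Spearman
   correlation over all genes, complete-linkage clustering on 1 − ρ, tree
   cut into k groups (default 2, configurable; the granularity a visual
   split would give). Groups with doublet over-representation (same Fisher
   criterion) or median UMI above the group-level 95th percentile are
   discarded; with k = 2 and unequal medians this removes the deeper group,
   which is intentionally conservative. Q1 of UMIs and of detected genes is
   computed over cells of the retained groups, and rescued barcodes must
   exceed both strictly. Fewer than four candidates: the rescue is skipped
   (quartiles would not be robust).

All percentiles and quartiles use linear interpolation (R type-7,
`numpy.percentile` default).

## PDX host/graft classification

Thresholds bound the **host**-read fraction h = host/(host+graft):
graft iff h ∈ [0, 0.1], host iff h ∈ [0.9, 1.0], ambiguous otherwise; band
ends inclusive, matching the threshold semantics of the upstream read-level
classifiers these counts come from. Zero-total barcodes have an undefined
fraction and are excluded from classification. The three labels partition
all classified barcodes.

## Synthetic data

The generator emulates what the pipeline *assumes*, with planted truth for
recovery testing:

- **Counts** are negative binomial (dispersion 2.0 by default) with a
  per-cell log-normal depth factor (σ = 0.3). Marker genes are silent
  outside their cluster (`marker_off_rate`, default 0) and boosted 20-fold
  inside it against a background mean of 2 counts/gene over 400 genes —
  yielding ~800 UMIs and ~300 detected genes per cell, comfortably inside
  the `biopsy` thresholds.
- **Doublets** are barcode collisions: an extra barcode whose count vector
  is exactly the sum of two parent cells (one from the host cluster, one
  from a random other cluster), so cross-lineage parents produce the marker
  conflicts the QC rules look for. Designated doublet clusters receive an
  elevated doublet fraction (default 50% vs 3% ambient).
- **Repertoire**: clone sizes follow a truncated power law (exponent 1.5
  over 400 clonotypes by default — clonal expansion with a long tail); each
  cell draws a clone, and its cluster is then drawn from reactive or
  background weight vectors depending on the clone's planted reactivity.
  One TRB plus one clonally consistent TRA per cell; a configurable fraction
  (5%) receives a second TRA to exercise the multi-alpha rule.
- **Reactivity sort**: each planted reactive clonotype is emitted with
  probability 1 − dropout with a positive read count; never a non-reactive
  one.
- **Species mixtures**: planted graft/host/ambiguous barcodes draw host
  fractions from [0, 0.1), (0.9, 1] and [0.3, 0.7] with integer-rounding
  margins, so exact label recovery is achievable and any error is an
  implementation bug.

What the generator does **not** model: transcriptome-wide co-expression
structure, ambient RNA, batch effects, sequence-level CDR3 grammar, or
doublet detectability limits — passing recovery tests shows the decision
rules are implemented correctly under the stated noise model, not that the
rules are optimal on real data.

## Calibration experiments (`trlmap.validation`)

Study conditions are fixed once and reused by the tests and the acceptance
script:

- **Null FWER**: 12 clusters with a shared non-uniform (Dirichlet-5) cluster
  distribution, 20,000 background cells vs 200 reactive cells per run, 1,000
  runs. The 100:1 ratio reflects real atlases, where the TIL-matching
  background dwarfs the reactivity-sorted subset. This matters: the binomial
  test treats the background frequency as *known*, so with small background
  pools the estimation noise is unmodeled and the test becomes
  anti-conservative (at 10:1 the family-wise error measurably exceeds the
  nominal level). This is a known limitation of the method itself, shared
  with any plug-in binomial background.
- **Planted enrichment**: one cluster holds 50% of reactive cells vs a 10%
  background share; analytic binomial power at n = 200 is ≈ 1, and recovery
  is required in ≥ 99/100 runs.
- **Doublet clusters**: 20 clusters × ~80 cells, two planted clusters at 50%
  doublets vs 5% ambient, 100 seeded atlas runs; recovery of both planted
  clusters and absence of false Fisher-criterion nominations are scored
  separately.
- **Species classification**: 20 seeded mixtures of 140 barcodes; zero
  tolerated errors.

Problem sizes were chosen so the full suite and the acceptance script each
run in about a minute on one CPU while keeping Monte-Carlo error small
relative to the asserted bounds.

## Determinism and numerics

Every generator takes an explicit seed (NumPy `default_rng`); the pipeline
itself is randomness-free, and a global run seed is expanded into per-stage
substreams by stable hashing of the stage name, so stages can be regenerated
in isolation. Reports contain no timestamps; identical config + seed gives
byte-identical outputs. Exact-test p-values are computed in log space from a
cached log-factorial table; observed agreement with exact rational
enumeration is ~10⁻¹⁴, bounded in tests at 10⁻¹².

## Known limitations

- β-only clonotype identity can merge distinct αβ clones sharing a β chain;
  this is inherent to matching against unpaired bulk data.
- The enrichment test conditions on the observed background; see the FWER
  note above.
- Doublet-cluster removal discards whole clusters; genuine biology co-
  clustering with doublets is lost by design (the procedure favors purity).
- The rescue step's group discard rule is conservative with k = 2 (the
  deeper candidate group is usually dropped when medians differ).
- The synthetic generator's independence assumptions make planted signals
  cleaner than real data; recovery rates reported by the acceptance script
  are upper bounds on real-data performance.
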