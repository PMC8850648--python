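# Methods

`xdosage` analyzes how X-chromosome copy number shapes the transcriptome in
sex-chromosome aneuploidies (47,XXY through 49,XXXXY) against 46,XY and
46,XX controls. This note records the models, the defaults and their
rationale, what the synthetic cohorts do and do not emulate, and the design
choices made where the analysis recipe was genuinely open.

## Genome/region model

The X chromosome is partitioned into PAR1 (first 2.6 Mb from the Xp
terminus), PAR2 (last 320 kb at Xq), and the non-PAR body; Y-linked genes
and autosomes complete the partition. PAR spans are configurable
(`ParBoundaries`); the defaults are the commonly cited human spans. A gene
straddling a PAR boundary is classified by its start position — a single
deterministic rule chosen because any per-base split would complicate every
downstream per-gene statistic for a handful of edge genes.

Internal coordinates are 0-based half-open. GTF is converted from 1-based
closed at read time, BED passes through, and SNP positions stay 1-based
(VCF convention) inside allele-count records. Chromosome names are
normalized (`chrX` ≡ `X`).

## Allele-specific expression (ASE)

Per-SNP reference-allele fractions are `refCount / totalCount` (the
denominator is the printed total, which may exceed ref+alt at sites with
other bases). A SNP is **biallelic** when the fraction lies in [0.1, 0.9] —
bounds inclusive, the literal reading of an "within the range" rule — and
**monoallelic** otherwise. A gene is biallelic iff at least one of its SNPs
is. Site filters, in order of precedence, keep SNPs that are: confirmed in
the exome-variant whitelist (PASS filter, total reads > 10), covered at
depth > 6, exonic, and uniquely mapped to one gene. XIST is exempt from the
unique-mapping filter and, by default, from the intronic filter too, since
its allelic status is the clonality readout for X inactivation (a biallelic
XIST indicates mosaic XCI and triggers a warning). Both exemptions are
configurable because the upstream convention is ambiguous.

Read-level filters (base quality, mapping quality) belong to the counter
that produced the table and are not re-applied here.

**Erosion flagging.** Cultured pluripotent cells can progressively lose X
inactivation ("X erosion"), visible as an excess of biallelic non-PAR X
genes. A sample is flagged when its biallelic non-PAR X count is at least
`multiplier_threshold` (default 2.0, reflecting the observed two-to-three-fold
excess) times the median of the other samples *and* at least `min_biallelic`
(default 30). The absolute floor is essential: 46,XY males contribute
near-zero counts (hemizygous X), dragging the cohort median down, and
without the floor ordinary escape-gene counts would trip the multiplier.

## Bulk dosage statistics

* **Expressed-gene filter**: genes with mean FPKM < 0.5 across the cohort
  are dropped. The aggregation rule (mean vs per-sample) is configurable;
  the mean is the default because it is stable for small replicate groups.
* **X:A ratio**: per-chromosome mean FPKM (MF = sum / n genes); the ratio is
  MF(X) over the unweighted mean of the 22 autosomal MFs. Exactly invariant
  under global rescaling. Dosage-compensated cells sit between 0.5 and 1.
* **Male-median fold change**: MM is the per-gene median over ≥2 healthy
  46,XY references (post expressed-filter); FC = FPKM / MM; MM = 0 genes
  are dropped with a log entry.
* **Moving average along X**: loess of log2 FC on gene start position,
  span 0.45 (fraction of points per window), local quadratic, tricube
  weights, no robustness iterations. The smoother is implemented here
  because no installed library exposes a degree-2 tricube loess; the local
  basis is centred on the evaluation point and scaled by the bandwidth to
  stay well-conditioned at genomic coordinates. log2 is the default scale
  (a raw-FC mode exists) since fold changes are displayed logarithmically.
* **DEGs**: thresholds FDR < 0.05 and |log2FC| > 0.25 (strict
  inequalities). The bundled engine is Welch's t on log2(CPM+1) with
  Benjamini–Hochberg — a deliberate substitute for a count-model engine,
  whose internals are out of scope; `call_degs` accepts any externally
  computed (log2FC, FDR) table unchanged.
* **Dosage trends**: per-gene OLS of log2(FPKM+1) on the sex-chromosome
  covariate — total sex-chromosome count for PAR genes (expressed from
  every sex chromosome), X count otherwise — with BH correction across
  genes; proportional/inverse requires corrected p < 0.05. Pseudocount 1
  guards zeros. X-linked DEG categories follow literature XCI status with
  PAR1 membership taking precedence; undescribed genes are "novel".

## Single-cell tests

Counts are library-size scaled to the median library and log2(x+1)
transformed; dropout imputation is intentionally not performed (the tests
operate on observed expression, and the synthetic generator does not
simulate the dropout process an imputer corrects). XIST dose across
karyotypes is compared by Kruskal–Wallis. Gene–XIST association uses
Pearson correlation **within karyotype only** — pooling karyotypes would
manufacture correlation through the shared dosage — and a gene is declared
XIST-independent when p > 0.05. That reading ("no significant correlation")
is an interpretation of an inverted-sounding significance convention, and
is the one consistent with reporting escape genes as dosage- but not
XIST-driven. Cell-cycle independence is Kruskal–Wallis across {G1, S, G2M}
with phases supplied externally (or by the generator); phase classification
itself is out of scope.

## Co-expression modules

Signed weighted-network recipe: adjacency `((1+r)/2)^β` with soft power
β = 20, signed topological overlap, average-linkage clustering. The tree is
cut **statically** at the 0.99 quantile of merge heights; clusters below
`min_module_size` = 30 go to "grey", and a cluster is accepted as a module
only if its mean within-cluster correlation reaches `min_intra_cor` = 0.3.
This coherence gate is the package's replacement for dynamic tree cutting
(not reimplemented): a quantile cut alone always produces clusters, even in
structure-free data, whereas the gate sends such clusters to grey. On the
generator's block designs the static cut + gate recovers planted modules
with ARI > 0.99 and assigns >90% of permuted-matrix genes to grey.

Module eigengenes are the first PC of the gene-standardized submatrix,
sign-oriented to correlate positively with the module mean profile.
Modules are filtered by one-way ANOVA across karyotypes (α = 0.05, the
conventional level) and labelled up/down when the eigengene regresses
significantly on the X count with monotone per-karyotype means; same-trend
modules with eigengene correlation ≥ 0.75 (dissimilarity < 0.25, the common
merge height) fuse into supermodules. Gene-set enrichment is the exact
hypergeometric upper tail with Bonferroni adjustment, and set overlaps
report count, percentage and the same exact p.

## Promoter motif enrichment

Promoters span −1,500..+500 bp around the TSS, strand-aware (minus-strand
windows are the mirrored genomic span, reverse-complemented). JASPAR count
matrices become probability matrices with a 0.01 per-cell pseudocount and
log2-odds scores against a uniform background (JASPAR matrices are counts;
the background is configurable). A window is a hit when its score is within
`deficit` × (s_max − s_min) of the maximum achievable score s_max —
deficit 0 accepts only consensus-scoring windows, deficit 1 everything;
default 0.15. Both strands are scanned; the reverse strand is scored by
scoring the reverse-complemented window with the forward matrix so that
consensus hits are float-exact on either strand. Enrichment is at gene
level ("coverage"): bound = ≥1 hit in the promoter, two-sided Fisher's
exact on bound/unbound × query/background, and a TF is "recurrent" when
significantly over-represented in ≥7 of the supermodule gene sets.
Background GC-matching (as some scanning tools offer) is not performed.

## Synthetic cohorts

The generator encodes the dosage laws the analysis is built to detect, so
every stage can be scored against known truth:

| gene class | expected expression |
|---|---|
| PAR1 | base × (n_x + n_y)/2 |
| PAR2 | base (flat — observed not to mirror dosage) |
| non-PAR escape | base × n_x |
| inactive X | base (active X only) |
| XIST | base × (n_x − 1) (zero in 46,XY) |
| autosome | base, with optional ±0.5·(n_x−1) log2-linear trend subsets |

Defaults: 400 autosomal, 200 non-PAR X (10% escape), 15 PAR1, 3 PAR2 genes
plus XIST; karyotype panel XY×4, XX×2, XXY×4, XXXY×4, XXXXY×4 (2–4
replicates per karyotype is cohort-realistic); per-gene base levels
log-normal (meanlog 3, sdlog 0.8) with X-linked bases scaled by 0.6 so
cohort X:A ratios land in the dosage-compensated 0.5–1 window; replicate
noise multiplicative log-normal with CV 0.2. Allele counts: SNPs per gene
Poisson(3); depths negative-binomial (mean 50); biallelic reference
fractions Beta(20, 20) — centred on 0.5 with spread that exercises but
rarely crosses the 0.1/0.9 gate; monoallelic leak 0.01. Truth tables give
per-gene laws, noiseless expectations, and per-gene/sample allelic status.
An eroded sample reactivates enough inactive non-PAR X genes to reach
`multiplier` × the escape baseline (default 2.5 × ≈20 ≈ 50 genes).

In single-cell mode every gene's mean is a function of karyotype alone, so
escape/PAR expression is conditionally independent of each cell's realized
XIST — the null hypothesis of the independence tests built in by
construction. Phases are assigned independently of XIST; a configurable
handful of autosomal genes is made phase-dependent for power checks. The
module generator plants block-correlated modules (within-module r ≈ 0.85
via a shared latent factor per module) whose means trend with n_x.

What the generator does **not** emulate: read-level artifacts, mapping
bias, batch effects, UMI/dropout processes, doublets, linked SNP phasing,
and realistic per-gene dispersions (dispersion defaults are chosen for test
power, not biological fidelity). Passing tests therefore demonstrate that
the statistics recover the structure they are defined on, not that they are
robust to every artifact of real sequencing data.

All generators draw from sub-streams deterministically derived from one
global seed: identical seeds give byte-identical outputs, and the
end-to-end pipeline rerun reproduces every data artifact bit-for-bit.

## Numerical choices and degenerate inputs

Zero-depth SNPs are filtered, never classified. Zero-variance genes (or a
zero-variance XIST group, e.g. 46,XY cells) make correlation verdicts
"undefined" rather than numeric. Constant expression rows are dropped
before network construction. Rank-deficient module submatrices fall back to
the mean profile. Loess requires ≥10 points and handles tied x by local
averaging. Fisher and hypergeometric tests use exact routines (verified
against enumeration to 1e−12); the within-[0,1] fraction bounds on the SNP
gate are inclusive on both sides.

## Problem sizes

Test and demonstration runs use desk-scale cohorts — ~620 genes × 18 bulk
samples, 150–500 cells per sample, 500-gene module designs, 50-cohort
erosion sweeps — sizes chosen so the full suite and the end-to-end pipeline
complete in minutes on one CPU while keeping every statistical check
adequately powered. All sizes scale up through `SimConfig` and the stage
parameters.

## Known limitations

The DEG engine is a normal-model substitute, not a count model; module
counts from the static cut are not comparable to dynamic-cut module counts
on real data; promoter scanning ignores GC-matched backgrounds; ASE assumes
the exome whitelist has already controlled RNA editing; one annotation
build per run (no liftover).
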