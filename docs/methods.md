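# Methods

This note documents the models, estimators, parameter choices and known
limitations of the pipeline, and what the synthetic data do and do not
establish about behaviour on real data.

## Data model and conventions

Genotypes are alternate-allele dosages in {0, 1, 2} with a dedicated
missing sentinel (never 0, which is a valid homozygous-reference call).
Internal coordinates are 0-based half-open everywhere; VCF positions stay
1-based at the I/O boundary and GFF/GTF 1-based closed intervals are
converted on read, so window arithmetic is uniform. Multi-allelic VCF
records are skipped and counted rather than split: splitting silently
changes site counts, and the scan statistics are defined for biallelic
sites. Site depth is taken from INFO/DP when present, else the sum of
per-sample FORMAT/DP; which source was used is recorded on the matrix,
because "coverage depth" is ambiguous between the two in common usage.

## SNP quality control

Three rules, each evaluated on the original (pre-filter) site set, then
the union of flags removed in one pass:

* **Quality**: remove QUAL < 20 (sequencing error > 1%). Sites at exactly
  Q20 are kept — the inclusive boundary is the natural reading of a
  "Q20 quality control" and is asserted in tests.
* **Spacing**: any two SNPs closer than 5 bp on a chromosome are both
  removed (a difference of exactly 5 bp is allowed); flagging is
  transitive along runs, so a cluster of near-adjacent calls is removed
  whole. The rule targets sequencing/alignment artifacts, which exist
  before any filtering — hence it sees pre-filter positions. Removal is
  not cascaded afterwards: deleting sites can only increase gaps, so a
  second pass could never create new violations.
* **Depth**: keep sites whose summed depth lies in
  [mean/3, 5 × mean], closed on both ends, with the mean anchored to the
  pre-filter site set (no iteration scheme is assumed; single-pass is the
  simplest consistent reading).

Average depth semantics: the rule anchors to *total* summed depth per
site; a per-sample-mean variant would only rescale both sides of the
comparison identically when sample count is constant across sites, which
it is here, so the choice is inert for complete data and the total is
used.

## Window statistics

Windows are 40 kb sliding with 20-kb steps (both configurable), starting
at multiples of the step while the start is inside the chromosome; final
windows truncate at the chromosome end.

**Nucleotide diversity.** Per site, the unbiased mean pairwise difference
among the n non-missing alleles sampled in a population,
π = 2·n_ref·n_alt / (n(n−1)); sites with n < 2 are skipped. Window
diversity is the sum of site π divided by the full window span in bp.
Normalizing by span (rather than by variant or accessible sites) matches
common θπ-ratio scan practice and keeps the ratio's numerator and
denominator on the same footing; the alternative changes absolute levels
but not ranks when the two populations share the site set.

**FST.** Weir & Cockerham (1984) two-population ANOVA components per
site — among-population (a), among-individual (b), within-individual
(c) — computed from allele counts and observed heterozygote counts with
pairwise deletion of missing genotypes. Windowed FST is the ratio of
sums Σa/Σ(a+b+c), which is stable in low-diversity windows where a mean
of per-site ratios is not. Negative window values are retained: clipping
would distort the empirical quantile used for outlier calling. The
original study cites a standard FST reference without printing the
estimator; WC84 is the field default for this design, and a Hudson-style
estimator is available behind a config switch for sensitivity analysis
(the two rank windows near-identically on strong signals, r > 0.95 in
tests).

## Sweep calling

log₂(π_control/π_selected) per window; a window where the selected
population's diversity is exactly zero with nonzero control diversity
maps to +∞ — the strongest possible signal — and is force-passed, while
the reported ratio threshold is the quantile of finite values. Windows
with zero diversity in both populations are excluded from ranking.
Thresholds are empirical (1 − top_fraction) quantiles (linear
interpolation) over rankable windows (≥ 1 usable SNP in both populations
by default); ties at a threshold pass. A window is an outlier iff it
passes both thresholds. Fewer than 20 rankable windows is refused — an
empirical 95th percentile over fewer windows is not meaningful.

Outlier windows are merged per chromosome and mapped to genes by any
≥ 1 bp overlap (half-open intervals; a gene ending exactly at a window
start does not overlap). The original study used region annotation whose
gene-assignment rule is not printed; any-overlap is the least-assumption
choice, and full containment is config-switchable.

## Population structure

Pairwise distance is allele sharing — the mean of |dosage_i − dosage_j|/2
over co-non-missing sites, in [0, 1]. The study's distance tool is not
documented; allele sharing is declared as an explicit substitute, with
1 − IBS exposed as a config synonym (identical under dosage coding).
Trees are built at the individual level by Saitou–Nei neighbor joining
(Q-criterion, deterministic smallest-index tie-break), negative branch
lengths clamped to zero with the deficit recorded. Bootstrap resamples
SNP columns with replacement (standard phylogenetic bootstrap semantics,
not sample resampling), rebuilds distance and tree per replicate, and
scores each internal bipartition of the full-data tree by its replicate
frequency × 100; the default replicate count is 1,000.

PCA standardizes each polymorphic site by 2p̂ and √(p̂(1−p̂)) (Patterson
normalization as in EIGENSOFT), mean-imputes missing entries (zero after
centering), and eigendecomposes the sample covariance exactly — at desk
scale (tens of samples) iterative solvers add nondeterminism for no
benefit. Scores carry a deterministic sign convention
(largest-magnitude loading positive).

## Expression

FPKM[g, s] = counts[g, s] / (mapped_reads[s]/10⁶ × exon_union_kb[g]),
with gene length the merged-exon union.

The DEG test is a deliberate simplification of the DESeq2 approach,
implemented from scratch: median-of-ratios size factors (geometric-mean
reference over all-positive genes; library-size fallback with a
warning); log₂ fold change of normalized group means with a 0.5
pseudocount (the fold-change rule is silent on zeros); per-gene NB
dispersion by method of moments on pooled within-group residuals
(α̂ = (s² − μ̄)/μ̄², floored at 10⁻⁸); a delta-method standard error from
the NB variance function; and a two-sided p-value. There is no
dispersion shrinkage across genes, no LFC moderation and no independent
filtering. Because the dispersion entering the standard error is itself
estimated from only n₁+n₂−2 residual degrees of freedom, the Wald
statistic is referred to a Student-t distribution with that df rather
than a normal: at 4-vs-4 the normal reference is visibly anticonservative
(~9% of null genes at p < 0.05 in simulation), while the t reference
holds the nominal level (~5%). This is the package's calibration choice,
verified by Monte Carlo in the test suite.

Calling uses the rule fold change > 2 or < 0.5 **and** p < 0.05, with
raw p by default — the literal form of the published rule — and
BH-adjusted p behind a flag; both columns are always emitted.

## Integration and enrichment

Candidates are the exact set intersection of sweep genes with the shared
DEG set (default: intersection across the supplied DEG tables, mirroring
the two-meat-breeds-versus-control design; union is switchable).
Enrichment is a plain upper-tail hypergeometric test per term with BH
adjustment; the gene-length bias correction of goseq (Wallenius) is
deliberately not implemented — it requires a probability-weighting
function estimated from data not available here — and the background
defaults to annotation ∩ counts genes. Term maps are user-supplied TSV;
no GO/KEGG retrieval is attempted.

## Synthetic data

The generator produces the *statistical signature* the scan targets, not
genealogies:

* Ancestral allele frequencies ~ Beta(0.8, 0.8) rescaled to (0.05, 0.95)
  (a mildly U-shaped spectrum away from fixation); per-population
  frequencies Balding–Nichols, p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so
  background differentiation is analytically controlled by F (default
  0.05: diverged breeds of one species).
* A sweep region deterministically transforms the selected population's
  frequencies: solve p′(1−p′) = r·p(1−p) on the same side of ½ so
  expected heterozygosity is multiplied by r (diversity_reduction), then
  move a further fraction b (differentiation_boost) of the remaining
  distance to the boundary. Truth windows — windows fully inside the
  region — are therefore exactly known.
* Diploid genotypes are binomial(2, p) per individual; QUAL values place
  a configured fraction below the Phred-20 boundary; site depth is
  gamma-Poisson around the mean depth (default 120 ≈ 15× per sample
  over 8 diploids, overdispersion 0.3) to exercise both depth tails.
* Counts are gamma-Poisson (NB) around log-normal gene means
  (natural-log mean 4, sd 1 — medians near 50 counts), with per-sample
  depth multipliers (log-normal, sd 0.15) recorded as truth for the
  size-factor test; n_de genes receive a 2^±lfc fold change in group 2,
  half up, half down. DE genes can be planted preferentially on the
  genes lying inside sweep regions so that end-to-end candidate recovery
  has known truth.
* Annotation tiles non-overlapping genes (2–4 exons) in equal slots per
  chromosome and then forces, for each sweep region, one gene strictly
  inside it and one spanning its start boundary — exercising both the
  containment and the partial-overlap paths of window→gene mapping.

All randomness descends from one master seed through named substreams
(genotypes / counts / annotation), so each stage is independently
reproducible and full runs are byte-identical.

What passing tests show — and do not. The generator induces no linkage
disequilibrium beyond Balding–Nichols sampling, no allele-frequency
correlation between adjacent sites, no mapping artifacts and no
GC-coverage structure. Recovery results on this data therefore validate
the *estimators and decision rules*, not robustness to the correlated
noise of real resequencing data. Likewise DEG calibration holds for NB
counts with gene-wise independent errors; real RNA-seq adds correlation
structure and outliers that the simplified test does not model.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the checks
sharp rather than large: 50k SNPs for null calibration (standard error
of mean window FST ≪ the ±0.01 band), 100k SNPs over 10 Mb for sweep
recovery, 8+8 samples (a realistic resequencing cohort per breed), 200
bootstrap replicates for support recovery, 2,000 genes × 10 seeds for
DEG calibration. The planted sweep region in the recovery scenario is
400 kb: at 40-kb/20-kb windows a 10-Mb genome yields ~500 rankable
windows, so the joint top-5% rule can flag at most ~25 — a region is
sized so its 19 interior truth windows fit inside that budget, keeping
full recall logically attainable. Quantiles use linear interpolation;
FST windows with zero denominator are undefined and excluded from
ranking; all tolerance constants (dispersion floor 10⁻⁸, pseudocount
0.5) are fixed, not data-dependent.

## Known limitations

* No haplotype-based statistics (XP-EHH, iHS) and no composite-likelihood
  sweep tests; the scan is the pure empirical-quantile rule, with no
  significance or FDR attached to outlier windows.
* The NB test's per-gene dispersion is noisy at small n; power is lower
  than a shrinkage estimator would give, and the t reference trades a
  little power for calibration.
* ANNOVAR-style coding-consequence annotation, read alignment, variant
  calling and transcript assembly are out of scope; the pipeline starts
  at a called VCF and a gene-level count matrix.
* Enrichment ignores gene length and any selection bias in the study
  set beyond its membership.
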