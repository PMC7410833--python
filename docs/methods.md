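# Methods

`rbpatlas` reimplements, as reusable library code, the computational
procedures used to build functional maps of RNA-binding proteins (RBPs)
from eCLIP, RNA Bind-N-Seq (RBNS), knockdown RNA-seq, ChIP-seq and
imaging-based localization data.  Every stage can be exercised end-to-end
on synthetic data with planted ground truth, so each estimator's recovery
of its planted parameter is a testable property.

## Coordinate conventions

All genomic intervals are 0-based half-open on a single synthetic
chromosome (BED convention).  The overlap predicate everywhere is an
intersection of at least 1 nt on half-open intervals; peak/feature
matching is strand-aware unless noted.

## Synthetic data generators

The generators are first-class, tested code, not fixtures.  Each is a pure
function of its parameters and one integer seed (NumPy `default_rng`;
library-level seeds are spawned from a single run seed, so nothing draws
hidden entropy).

**Transcriptome** (`make_transcriptome`).  Genes are laid out sequentially
with 2-5 kb intergenic gaps: mostly multi-exon protein-coding genes (3-6
exons, 120-320 nt; introns alternate 1.2-2.6 kb and 0.3-0.9 kb so that
both distal-containing and proximal-only introns occur), plus one tRNA,
one miRNA and occasional two-exon noncoding genes.  The CDS starts and
ends inside the terminal exons, so 5'UTR and 3'UTR exist for every coding
gene; some genes carry a second isoform that skips an internal exon and
shortens the CDS, which instantiates within-gene CDS/3'UTR annotation
conflicts.  Expression is log-normal TPM per cell type.  The repeat
database carries one primary transcript (priority 1) plus two pseudogenes
per family and a single combined simple-repeat family; antisense
counterparts exist implicitly for every non-simple family.

**eCLIP reads** (`simulate_eclip`).  Input reads are sampled over genes
proportionally to TPM x gene length (position uniform within the gene, a
deliberate simplification: no exon structure in coverage), plus a constant
baseline abundance for repeat transcripts.  IP replicates re-weight repeat
families by the planted selection weight and multiply the sampling density
by lambda wherever a fragment overlaps a planted element; this is enforced
by acceptance sampling, so the planted IP/input density ratio is exact in
expectation and recoverable within binomial sampling error.  Reads carry
10-nt UMIs; PCR duplication copies a record verbatim (new read id, same
coordinates and UMI) with probability `dup_rate`, matching the
(target, start, stop, UMI) dedup key.  Not modelled: sequencing errors,
fragment-length distributions, crosslink-position bias.  Tests passing on
these data therefore show the estimators are correct under the stated
sampling model, not that they are robust to those real-data artefacts.

**RBNS pools** (`simulate_rbns`).  Input reads are uniform random RNA
oligos of fixed length (default 20 nt).  The pulldown distribution is the
input distribution exponentially tilted by `s**m`, where `m` is the number
of overlapping occurrences of the planted consensus and `s >= 1` the
per-occurrence selection factor.  Sampling is exact: the occurrence-count
law P0(m) is computed by dynamic programming over the motif's KMP
automaton, m is drawn from the tilted law, and a read is drawn uniformly
among reads with exactly m occurrences (plant-and-check construction with
an importance correction for overlapping plants).  Because the model is an
exponential tilt, the expected R value of any k-mer has a closed form
(`expected_r_value`, a product-automaton DP verified against brute-force
enumeration at small read length), which serves as the analytic reference
for recovery checks.

**Knockdown tables** (`simulate_kd_tables`).  Control inclusion levels
follow Beta(2, 2) — the distribution of native cassette-exon inclusion is
a free modelling choice here and is configurable.  Null events draw
p ~ Uniform(0, 1) and a Normal(0, 0.01) dpsi jitter; planted events get
their planted dpsi and a p-value drawn from Beta(0.05, 1) rescaled into
(0, 1e-4).  The rescaling (rather than a raw Beta draw) makes "planted
implies significant" a construction guarantee at the p < 0.05, FDR < 0.1,
|dpsi| > 0.05 thresholds even after Benjamini-Hochberg adjustment across a
mostly-null table.  Gene tables carry TPM per cell type, log2 fold-change
and BH-adjusted p-values with the same planted/null split.

**ChIP peaks** (`simulate_chip`).  Peak centres land in 1-kb TSS windows
with `promoter_bias : 1` odds against a uniform proposal (acceptance
sampling again, so bias 1 reproduces the genomic promoter base fraction);
the signal track is a unit baseline plus a rectangular lift under each
peak.

## Repeat-family quantification

Mappings of one read pair are filtered to the lowest mismatch count;
among equal-scoring mappings the highest-priority transcript in a family
is the primary match, and pairs whose best score spans two or more
families are discarded (reverse-strand mappings belong to the antisense
counterpart family, except simple repeats, which are one family).  A
unique genomic mapping beats the repeat mapping only when its pair
alignment score is better by strictly more than 24 — the boundary case
(exactly 24) keeps the repeat mapping.  PCR dedup keys on
(target, start, stop, UMI); the survivor is the lexicographically smallest
read id, a stable order-independent choice that leaves counts unaffected.
Depth normalisers count all usable deduplicated pairs including unique
genomic ones; discarded multi-family pairs are excluded.

Relative information per element is p_i log2(p_i / q_i) bits, with p_i and
q_i the fractions of total IP and input reads on element i.  When exactly
one of p_i/q_i is zero it is replaced by half the reciprocal of the larger
library depth (a pseudo-fraction; both-zero elements contribute 0 bits).
The merged-replicate variant uses the average IP fraction of the two
replicates as p_i.  Element granularity defaults to repeat families plus
transcript-region groups and is configurable.

Region-level signal uses the two-sided Fisher exact test, replaced by the
Yates-corrected chi-square when all observed and expected cells exceed 5;
a region is eligible when one library has >= 10 reads and the other is
expected to have >= 10 given the depth ratio, and significant at fold >= 4
and p <= 1e-5.

## Peaks

Replicate peaks are matched by >= 1 nt same-strand overlap (largest
overlap wins), merged to the interval union, and scored by the geometric
means of log2 fold enrichment and -log10 p.  Reproducibility is an
injectable scorer.  The default is a rank-consistency surrogate: peaks are
ranked by enrichment within each replicate and the irreproducibility score
is the absolute difference of normalised ranks, with peaks kept at scores
up to sqrt(threshold).  This preserves the documented threshold semantics
(identical replicates all pass; stringency grows as the cutoff shrinks)
while isolating the one component whose exact parametric form is not
pinned down here; a full IDR implementation can be swapped in through the
`scorer` argument.  The final filter is merged fold >= 8 and merged
p <= 0.001, followed by blacklist removal (>= 1 nt overlap with a
user-supplied interval list; the blacklist is an input file and the
package makes no claim about its size).

Annotation assigns exactly one of 11 labels.  Within one gene the priority
is tRNA > miRNA > miRNA-proximal (500 nt) > CDS > 3'UTR > 5'UTR > 5'
splice site (100 nt) > 3' splice site (100 nt) > proximal intron (500 nt)
> distal intron > noncoding exonic; across genes the order changes to
tRNA > miRNA > CDS > 3'UTR > 5'UTR > miRNA-proximal > noncoding exonic >
5'ss > 3'ss > proximal > distal intron.  Peaks outside every gene are
"intergenic" (an explicit extension).  The implementation is checked
against a naive exhaustive rule-table oracle on annotations constructed to
instantiate the pairwise conflicts.

Cross-cell preservation classifies genes by TPM fold-difference
(<= 1.2 unchanged, <= 2 weak, <= 5 moderate, > 5 strong, all requiring
TPM >= 1 in both cells; < 0.1 vs >= 1 is cell-type-specific; everything
else "other"), recomputes each peak's fold enrichment from the other
cell's coverage, summarises the >= 4-fold-preserved and not-enriched
(<= 1) fractions per class, and compares classes by two-sided
Kolmogorov-Smirnov tests.  Saturation analysis shuffles dataset order
(default 100 shuffles) and reports cumulative union sizes; base-coverage
fractions are computed on the highest-expressed isoform per gene (ties
broken lexicographically by transcript id).

## RBNS and motif comparison

R = pulldown k-mer frequency / input frequency with overlapping
occurrences counted and 0.5 pseudo-occurrences added to every k-mer in
both libraries (prevents division by zero; affects only vanishing-
frequency tails).  Z standardises R across all 4^k k-mers (population
moments, so mean 0 / sd 1 hold by construction).  Among concentrations the
library with the highest single k-mer R is selected.

Logos iterate: take the top 5mer by current (masked) R — ties resolve
lexicographically, which the index order provides for free — weight it by
R - 1, mask all its occurrences in both libraries with a sentinel that can
seed no k-mer, recount, and stop when the newly found top 5mer's Z
computed from the original unmasked R values drops below 3 (2.8 for eCLIP
logos, the threshold that makes eCLIP logos comparable in size).  Accepted
5mers align to the seed of an existing motif when mismatches plus |offset|
is at most 2 (offsets tried in order 0, -1, +1, -2, +2; the first motif
that accepts wins), else seed a new motif.  The PWM weights covered
positions by the member weights, assigns 25% pseudocounts per nucleotide
at unaligned flanks, trims outer positions with more than 75% unaligned
weight, and normalises columns.  The split-half filter reruns the
iteration on each half of the data (for eCLIP: on each replicate peak set
with its own matched background) and keeps only 5mers recovered in both;
"corresponding logo" matching is by membership in either half's accepted
set, a documented simplification.

eCLIP backgrounds preserve gene, region class and peak length; intronic
and CDS backgrounds additionally preserve the peak start's distance to the
closest intron-exon boundary.  Peaks with no feasible background position
are dropped and logged.  Motif-set overlap uses the upper-tail
hypergeometric p against the universe of 1,024 5mers (significant at
p < 0.05).  RBNS+/- classification scans the peak extended 50 nt upstream
of its 5' end.  Matched controls are drawn without replacement from the
same joint decile of wild-type expression and psi (decile edges computed
on the pooled candidates); splicing-effect comparisons use one-sided
Wilcoxon rank-sum tests on |dpsi| (exact enumeration for tie-free groups
of at most 25, normal approximation with tie correction above).

## Splicing maps

Significant events need rMATS-style p < 0.05, FDR < 0.1 and |dpsi| > 0.05
(dpsi = psi_KD - psi_control; positive = included upon knockdown); native
cassette exons have control psi in (0.05, 0.95) and are not significant.
The meta-region stacks four splice-site boundaries (upstream-exon end,
event 5'ss, event 3' end, downstream-exon start), each with 50 exonic +
300 nt intronic positions by default (1,400 positions total for cassette
exons), transcript-oriented so left is always upstream; positions beyond a
short feature are masked, not zero-filled.  Per-position density is IP RPM
minus input RPM (the combiner is a strategy; a ratio mode exists); each
event's density vector is then scaled by its total absolute mass before
averaging, so that a few highly expressed genes cannot dominate the event
mean (this per-event normalization is the package's resolution of a point
the reference methodology leaves open; without it the native band is
visibly mis-calibrated under the null).  The map is the event mean minus
the native-event mean, and the band is the 0.5th/99.5th percentile of
means from 1,000 seeded without-replacement samplings of native events of
matched size; when the matched size would exhaust the native pool the
sampler falls back to a bootstrap so the band keeps nonzero width.
Overlapping events are retained.  Map correlation concatenates the KD-included and KD-excluded
vectors (a class below its minimum — 100 cassette exons, 50 alternative
splice-site events — is dropped; NaN when none qualifies).  Cross-RBP maps
apply one RBP's events to another's densities, with class averages framed
by 10th-90th percentiles.  The per-exon RBP profile counts, per position,
the RBPs with a reproducible peak, averaged over exons (spliceosomal RBPs
are excluded by the caller's roster).  MXE and RI events are limited to
raw density export; the map machinery covers SE, A3SS and A5SS.

## Integration statistics

Differential expression strength: strong |log2FC| >= 2, moderate (1, 2),
weak <= 1.  Splicing strength: strong |dpsi| >= 0.30, moderate
[0.15, 0.30), weak (0.05, 0.15).  Tandem-UTR events are significant when
|Bayes factor| >= 5 and p < 0.05 hold in all four pairwise comparisons and
both grouped orderings.  Binding/DE overlap runs only when more than 10
genes changed, against the eligibility-passing background, with Fisher or
Yates (same >5 rule) and Bonferroni correction across the executed
comparisons only (skipped comparisons do not enter the family size).
KS comparisons between enrichment categories are two-sided.

ChIP-eCLIP: base-level Jaccard indexes split at 1-kb TSS windows
(promoter vs non-promoter); signal enrichment compares mean ChIP signal
inside gene-body eCLIP peaks (gene span minus 1-kb TSS/TTS windows,
strand-aware) against flanks of 10x the peak length per side (truncated at
chromosome ends and flagged), one-sided rank-sum across peaks, significant
at p <= 0.001 with no multiple-testing correction, by design.  The
TSS-binding/DE dependence test samples, per round, equal numbers of bound
and unbound genes from the same TPM decile ("similar expression" is
implemented as decile matching, mirroring the matched-controls procedure),
builds the 2x2 table with odds ratio (a/b)/(c/d), applies a one-tailed
Fisher test, and declares dependence when the null is rejected at 0.05 in
at least 95% of 100 rounds.  Localization associations are one-sided
rank-sum tests of relative information between labelled and unlabelled
RBPs; nuclear means nuclear:cytoplasmic ratio >= 2, cytoplasmic <= 0.5.
Spliced reads span an annotated junction with >= 10 nt in each exon;
unspliced reads cross an exon-intron boundary with >= 10 nt on each side;
reads shorter than 20 nt are never classified.

## Numerical choices and degenerate inputs

- Fisher's exact test uses the minimum-likelihood two-sided definition;
  the test suite checks it against exhaustive hypergeometric enumeration
  for every 2x2 table with all margins <= 30 at 1e-9.
- Zero-variance inputs: Z-scores of a constant R vector are all zero; an
  all-zero ChIP track reports not-applicable; empty interval unions give
  Jaccard 0 by convention (logged).
- Fold enrichment with zero input coverage is +inf when IP is positive,
  NaN when both are zero.
- All percentile bands use NumPy's linear-interpolation percentiles.

## Problem sizes

Library defaults match the scales the analyses assume (RBNS pools of
2x10^5 reads, 1,000 native-event samplings, 100 resampling rounds).  The
shipped pipeline configuration and the calibration studies in the test
suite run at reduced scale — tens of genes, 10^4-10^5 reads, tens of
calibration replicates — chosen so the full suite exercises every stage
while remaining quick to run on a laptop; the statistical checks state
their Monte-Carlo tolerances accordingly.

## Known limitations

- The reproducibility scorer is a documented surrogate, not a fitted IDR
  mixture model; only the threshold semantics and the injectable interface
  are guaranteed.
- The generators omit sequencing error, fragment-length variation and
  crosslink-site bias; conclusions about robustness to those effects
  cannot be drawn from these tests.
- Whether RBNS R values share one input library across concentrations is
  configurable (default: shared input).
- MXE/RI splicing-map geometry, tandem-3'UTR maps, GC normalisation,
  batch correction and clustering runs are out of scope; the package
  exports the vectors those external steps consume.
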