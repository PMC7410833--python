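# rbpatlas

Analysis toolkit for building functional maps of RNA-binding proteins
(RBPs): repeat-family-aware eCLIP quantification with relative
information, reproducible peak filtering and priority annotation, RNA
Bind-N-Seq (RBNS) k-mer enrichment and iterative motif logos,
input-normalised RNA splicing maps with resampled percentile bands, and
the overlap statistics that connect in vivo binding to expression,
chromatin association and subcellular localization.

It is written for computational biologists who work with CLIP-style
binding data alongside perturbation RNA-seq: every stage is a library
function over plain tabular/BED/FASTA inputs, and a synthetic-data module
generates inputs with planted ground truth (enrichment folds, motif
selection strengths, delta-psi effects) so each estimator's recovery of
its planted parameter is a testable property.

## The statistics at the core

- **Relative information.** For element *i* with fraction *p_i* of IP
  reads and *q_i* of input reads, the signal is *p_i* log2(*p_i*/*q_i*)
  bits; repeat-family counts come from a priority-aware assignment in
  which a read pair maps to the highest-priority transcript of a single
  family (multi-family ties are discarded), a unique genomic alignment
  wins only when it beats the repeat alignment by more than 24 pair-score
  points, and PCR duplicates collapse on (target, start, stop, UMI).
- **RBNS enrichment.** *R* = pulldown k-mer frequency / input frequency;
  *Z* standardises *R* across all 4^k k-mers.  Motif logos iterate:
  weight the top 5mer by *R* − 1, mask its occurrences in both libraries,
  recount, stop when the original-scale *Z* falls below 3 (2.8 for eCLIP
  logos), align accepted 5mers within a budget of two mismatches plus
  offsets, and keep only 5mers recovered in both half-splits (replicates,
  for eCLIP).
- **Peaks.** Replicate-merged scores are geometric means of log2 fold
  enrichment and −log10 *p*; reproducible peaks require an injectable
  reproducibility score at the 0.01 cutoff plus fold ≥ 8 and *p* ≤ 0.001,
  then blacklist removal.  Annotation resolves the 11 region labels by
  the within-gene and cross-gene priority orders.
- **Splicing maps.** Per-position IP-minus-input RPM over a meta-exon
  (50 exonic + 300 intronic nt per splice-site boundary), averaged over
  knockdown-responsive events (*p* < 0.05, FDR < 0.1, |Δψ| > 0.05),
  normalised against native cassette exons (control ψ in 0.05–0.95) and
  framed by the 0.5th/99.5th percentiles of 1,000 matched-size native
  resamplings.
- **Integration.** Fisher/Yates 2×2 overlap tests with the >5
  observed-and-expected rule, two-sided Kolmogorov–Smirnov comparisons by
  enrichment category, base-level Jaccard indexes split at 1-kb promoter
  windows, flank-normalised ChIP signal at eCLIP peaks, and an
  expression-matched resampled odds-ratio test ((a/b)/(c/d), dependence
  declared at ≥95/100 rejections).

See `docs/methods.md` for the full model descriptions, parameter defaults
and design decisions.

## Worked example

Recover a planted RBNS motif and build its logo:

```python
from rbpatlas.simulate import simulate_rbns, expected_r_value
from rbpatlas.rbns import kmer_r_values, build_rbns_logos

pulldown, inp = simulate_rbns("UGCAUG", s=10.0, n_reads=200_000, seed=1)
profile = kmer_r_values(pulldown, inp, k=5)
print(profile.top_kmer(), round(profile.r.max(), 3),
      round(expected_r_value("UGCAUG", 10.0, profile.top_kmer(), 20), 3))
logo = build_rbns_logos(pulldown, inp)[0]
print(logo.consensus(), round(logo.motif_fraction, 2))
```

```
UGCAU 3.182 3.191
UGCAU 1.0
```

The top 5mer is one of the two 5mer cores of the planted 6mer; its
observed enrichment (R = 3.182) sits within Monte-Carlo error of the
closed-form model expectation (3.191), and the logo builder returns a
single motif containing all of the signal (motif fraction 1.0).

The full pipeline — simulate, quantify repeat families, call and annotate
reproducible peaks, discover motifs, build splicing maps, run the
integration statistics — is one command:

```bash
atlas run --seed 11 --out atlas_run
```

which writes read records, family quantifications, peak and event tables,
the splicing map with its percentile band, and a `manifest.json` with
per-file SHA-256 digests; rerunning with the same configuration and seed
reproduces every file byte-for-byte.

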