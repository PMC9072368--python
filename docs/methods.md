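# Methods

## The measurement model

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while m⁵C resists conversion. At a transcript position with true
methylation level *m*, the probability that a well-converted read reports C
is `m + (1 - m) * (1 - c)`, where *c* is the library's conversion rate for
that gene (typically 0.99-0.999). Two noise processes are modelled
explicitly:

- **Per-base non-conversion** at rate `1 - c`, handled by the gene-specific
  one-sided binomial test: a site's unconverted count against
  Binomial(coverage, 1 - c), with *c* estimated per gene over all
  high-quality observations outside candidate sites (excluding candidates
  avoids circularity; genes with fewer than 50 informative observations
  inherit the library-wide rate).
- **Whole-read conversion failure**: a minority of RNA molecules escape
  conversion entirely, so every C on such a read stays C. These are removed
  by the C-cutoff filter (reads with more than *k* unconverted Cs), with *k*
  selected where the Gini coefficient of candidate-site levels stabilizes
  as the cutoff decreases; the signal ratio (fraction of a site's
  unconverted reads surviving the filter, threshold 0.9) then rejects sites
  whose apparent signal was carried by removed reads.

The cascade order is: coverage, variant count, level, post-C-cutoff
re-check, signal ratio, conversion-resistant gene, binomial test, replicate
agreement. The audit table records the first failing filter for every
candidate (candidacy uses the loose all-quality gate of ≥ 3 unconverted
reads at level ≥ 0.1, so near-miss positions are audited rather than
silently dropped). With two replicates a site needs a full single-replicate
call in at least one replicate, presence (post-filter level ≥ 0.1) in the
other where covered, and a Stouffer-combined p < 0.001; a site covered ≥ 20×
in only one replicate instead needs ≥ 5 unconverted reads there.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| min_coverage | 20 | reads | quantification below ~20× is too noisy for a 10% level floor |
| min_level | 0.1 | fraction | level floor for a confident site |
| min_variant_reads | 3 | reads | minimum unconverted support at Q ≥ 30 |
| min_base_qual | 30 | Phred | drops miscalled bases from pileups |
| c_cutoff | 3 | C obs/read | Gini-stabilized read filter; diagnostic exposed per run |
| min_signal_ratio | 0.9 | fraction | signal must survive removal of failure reads |
| resistant_gene_max_nonconversion | 0.05 | fraction | genes above this (≥ 50 obs) are structurally conversion-resistant; their sites are suppressed |
| p / combined_p threshold | 0.001 | — | fixed cutoffs, no FDR correction (thresholds, not ranked discovery) |
| single_rep_min_variant | 5 | reads | stricter support when replicate confirmation is unavailable |
| min_pair_coverage (conservation) | 10 | reads | pair-inclusion gate; certifying "unmethylated" additionally needs ≥ 20× and level < 5% |

A strict-inequality epsilon (1e-12) keeps rates exactly at the resistant
threshold from being flagged through binary rounding.

## What the synthetic data emulates — and what it does not

The generator produces annotated transcriptomes (5'UTR/CDS/3'UTR, optional
per-bin GC targets), plants Type I sites (downstream GGG) and Type II sites
(downstream U,C,N,A) at levels ≥ 10% with at least 120 nt spacing (a few
sites per mRNA, matching heavily methylated maternal transcriptomes; the
spacing also means a 100 nt read rarely spans two methylated sites, which
is what makes a small C-cutoff safe), and simulates single-end reads in
transcript space with the two noise processes above plus a two-point base
quality mixture (Q37 with probability 0.99, else Q20) to exercise the
quality filter. Species pairs are derived by uniform point substitutions;
methylation retention in the second species is drawn from a logistic model
over the second species' own context features, with substitution of the
site C forcing loss.

Not emulated: splicing and genome-space alignment, indels, PCR duplicates,
position- or sequence-dependent error profiles, 5-hydroxymethylcytosine or
other partially resistant marks, and covariation between expression level
and coverage. Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated noise model, not robustness to
alignment artifacts or library-specific biases in real data.

Structure features for the species-pair generator are stochastic
single-stem hairpins (valid dot-brackets with varying loop center, loop
size and stem length) rather than folded sequences: structures are inputs
throughout the package, and the hairpin model gives every window position
non-degenerate pairing variance, which folding short random windows does
not. A maximum-base-pairing dynamic program (`fold_minimal`, AU/GC/GU
pairs, minimum loop 3) is provided for users without external structures;
it is a combinatorial optimum, not a thermodynamic prediction, and folding
temperature is carried only as metadata for external folders.

## Numerical choices

- Binomial tails are exact (`scipy.stats.binom.sf`); the test suite checks
  them against direct summation to 1e-12.
- Stouffer combination works on upper-tail normal quantiles; p-values are
  clipped to [1e-300, 1 - 1e-12] before combination to survive underflow.
- The logistic GLM is fitted by IRLS with an optional ridge epsilon
  (default 1e-6) stabilizing quasi-separated designs; with the ridge
  disabled it matches a plain Newton oracle and statsmodels to 1e-6.
  Complete separation is reported as non-convergence, never as a silent
  estimate. Dummy coding drops the most frequent base per position.
- The bootstrap structure test down-samples 100 contexts per group without
  replacement, 1000 times; one-sided direction is the sign of the
  full-data frequency difference, and both one- and two-sided p-values are
  reported. Because all positions of a replicate share the same resample,
  per-position p-values are correlated; the null rejection rate is
  calibrated in aggregate, not per position independently.
- Metagene bins use floor(f · n) on the region-local fractional coordinate
  with clamping into the region's last bin, keeping region bins disjoint;
  bin-count derivation rounds half away from zero. Empty background bins
  report missing density, not zero.
- Gini uses the sorted rank form of the mean-absolute-difference formula;
  C-cutoff selection takes the smallest cutoff whose Gini differs from the
  next by < 0.02, falling back to the largest candidate when nothing
  stabilizes.
- Coordinates are 0-based half-open internally, 1-based in exported tables.

## Design choices that were genuinely open

- **Signal ratio** is defined as post-filter over pre-filter unconverted
  counts at the site, making the 0.9 threshold mean "at most 10% of the
  signal came from removed reads". Other definitions are conceivable; this
  one is monotone in the filter's effect and dimensionless.
- **Type II registration**: the motif is read downstream of the site
  (+1..+4 = U,C,N,A), consistent with tolerance of non-C bases at +3; the
  alternative centered registration (C,U,[site],N,A) is available via a
  config switch.
- **Conservation coverage gates**: pair inclusion at ≥ 10× and
  unmethylated certification at ≥ 20× are applied together, so both
  thresholds can hold simultaneously; summaries report conserved
  percentages against both the determinate and the all-paired denominator.
- **Gain/loss design**: the case-control construction contributes the
  methylated species' context as a positive row and the unmethylated
  species' as a negative row, restricted to C/C pairs methylated in exactly
  one species. Parameter-recovery validation instead fits retention against
  the second species' features directly, because that is the generative
  model; the case-control fit is a contrast, not an estimate of the
  generating coefficients.

## Problem sizes

Validation runs use 200 genes (~2.2 kb transcripts, ≥ 10⁵ covered
cytosines) at 60× with two replicates for caller fidelity; 4000 ortholog
pairs for GLM recovery; 2000 pairs for conservation recovery; 300 contexts,
1000 bootstrap replicates for the structure-test calibration; and a
256-variant pool at 200 reads/variant for the mutagenesis round trip.
These sizes give the quoted binomial error bands while keeping a full
validation run around a minute.

## Known limitations

- The caller assumes sense-strand transcriptome alignments; genomic-strand
  resolution must happen upstream (the SAM adapter rejects reverse-strand
  records).
- Gene conversion rates assume one transcript per gene in the bundled
  generator; isoform collapsing is the caller's responsibility only through
  the supplied annotation.
- The Type I pairing feature set (±50 nt, 101 binary features) is large
  relative to typical non-conserved site counts; the default ridge epsilon
  stabilizes the fit but coefficients on sparse positions have wide
  standard errors.
- Percent-style thresholds (10% / 5%) are applied to point estimates of
  levels; no shrinkage or interval-based calling is attempted.
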