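# Methods

## Scope and data model

`snptrack` operates downstream of alignment and SNP calling: its inputs are
per-sample lists of already-called single-nucleotide substitutions, and its
outputs are tables, cross-sample summaries and UCSC custom tracks. It does
not call variants, handle indels, or perform any statistical test on the
frequencies it reports — the comparison is a descriptive occurrence count
intended for candidate ranking, and analyses are per-chromosome.

A call is `(chrom, pos, ref, alt, score, counts, extras)` with `pos`
1-based. Chromosome labels are normalized on input (leading `chr` stripped,
`M`→`MT`; accepted set 1–22, X, Y, MT) and ordered numerically with X, Y, MT
last. Across samples a SNP's identity is the key `(chrom, pos, alt)`;
an optional position-only mode relaxes this to `(chrom, pos)` for callers
that disagree on the alternate allele. Within a file, duplicate keys keep the
first occurrence with a warning (an error under `--strict`).

### Score and missing values

The native format's rule is that any missing value is written as `0`; a
score of 0 is therefore flagged "missing" but carried verbatim — never
imputed, never dropped — and survives round trips. Scores are otherwise
treated as opaque non-negative numbers (MAQ-era callers used Phred-like
scales, but nothing here depends on that).

### Count-column dialects

"Number of reads of each nucleotide" was serialized differently by
different upstream callers, so the reader supports three explicit layouts:
`four_nt` (A,C,G,T order; default), `ref_alt` (consensus count, SNP count),
and `total` (a single depth). Under `total` the depth is stored under the
alternate allele and the record is flagged so every per-allele quantity
(mutant fraction, zygosity, pgSnp conversion) reports *unavailable* rather
than a fabricated number. The sniffer counts the run of integer columns
after the score and prefers `four_nt` > `ref_alt` > `total`; explicitness
beats guessing, so the dialect can always be forced.

## Zygosity classification

The mutant-read fraction is `counts[alt] / total`. The default band
(0.2, 0.8) is the conventional diploid read-fraction heuristic: fractions
≥ 0.8 are called homozygous-alternate, [0.2, 0.8) heterozygous, < 0.2
ambiguous (too few mutant reads for a confident genotype). The boundaries
are inclusive-low by design (`f == 0.8` is `hom_alt`, `f == 0.2` is `het`)
and fully configurable, since the appropriate band depends on depth and
contamination. Rendered tables show the percentage at one decimal place
while keeping the full-precision fraction in a separate column.

## Sample comparison semantics

For each key present in at least one of the *N* selected datasets, the
frequency is `count / N`, where *N* is the number of datasets passed to the
comparison — not all datasets ever loaded — matching the select-then-compare
workflow. The threshold filter is **inclusive** (`frequency ≥ t`), so
`t = 1.0` selects SNPs fixed in the selection. Entries sort by frequency
descending, ties broken by genomic order (chromosome rank, position, alt)
for determinism. The presence matrix is defined over the same key union, so
its row sums equal the comparison counts identically; this cross-consistency
is asserted in the test suite and the acceptance script.

## pgSnp conversion

pgSnp lines are `chrom chromStart chromEnd name alleleCount alleleFreq
alleleScores` with 0-based half-open coordinates: a SNP at 1-based `pos`
maps to `[pos-1, pos)`. Choices where the upstream format underdetermines
the output:

* **alleleScores** — upstream carries one score per call, pgSnp wants one
  per allele; the call score is replicated across alleles (lossless,
  explicit).
* **alleleFreq** — observed read counts, not fractions, per UCSC convention.
* **zero-read alleles** — omitted from `name` by default so homozygous
  calls render as a single allele; `keep_zero_alleles` restores them.
* **third alleles** — reads on a nucleotide that is neither consensus nor
  SNP allele are ignored with a warning (the format has no slot for them);
  `include_third_allele` emits them.
* chromosomes take the `chr` prefix, `MT` → `chrM`; lines are emitted
  sorted by (chromosome, start) for byte determinism.

A parser re-reads track files and enforces every invariant (7 fields,
interval length 1, token-arity agreement) with line numbers, supporting
lossless round trips.

## Synthetic cohorts

The generator emulates a small resequencing study of related/affected
individuals. Defaults: 5 samples, 200 SNPs over chromosomes 1–2, 30×
expected depth, 1% per-read miscall rate, 50% of carrier calls
heterozygous, 30% of SNPs shared by all samples and 30% private to one, the
remainder assigned to uniform random subsets of intermediate size (for 2–3
samples that range collapses to pairs). Read counts follow the simplest
model sufficient to exercise every code path: depth Poisson(mean), mutant
reads Binomial(depth, 0.5) for het and all reads mutant for hom-alt, each
read miscalled with the error probability to a uniformly chosen other
nucleotide. Scores are uniform integers 20–90 with a 5% missing (`0`)
fraction. Positions are unique per chromosome, so presence counting over
generated files is noise-free and must reproduce the returned truth table
exactly. Everything derives from one `numpy` generator seeded by the spec,
so identical specs yield byte-identical files.

What this model deliberately omits: real error profiles (quality decay,
strand bias), mapping artefacts, linkage between sites, and indels. Passing
tests therefore demonstrate correctness of the bookkeeping — counting,
thresholding, conversion, serialization — under a clean diploid sampling
model, not robustness to messy real-world calls.

With the default band, misclassification of a het call at depth *d* requires
the binomial fraction to leave [0.2, 0.8); averaged over Poisson(30) depth
this is ≈0.1–0.2%, which is why the 99% recovery check at 30×/1% error holds
with margin.

## Numerical and degenerate-input choices

* Frequencies are exact small rationals (`count / n_samples` in floating
  point); no tolerance is needed anywhere in the comparison path.
* Zero total depth → mutant fraction and zygosity *unavailable*, never 0/0.
* A chromosome absent from every dataset yields an empty table plus a
  warning, not an error.
* Empty files, malformed lines (wrong arity, bad nucleotides, `ref == alt`,
  non-integer counts, position < 1) are diagnosed with line numbers; the
  parser never drops a line silently (the only documented skip is non-SNV
  records during VCF import, which is counted and returned).
* Writers end files with a trailing newline and use `\n` regardless of
  platform; readers accept CRLF.

## Problem sizes

The test suite and `scripts/acceptance.py` use cohorts of up to 10 samples ×
500 SNPs (hundreds of randomized cohorts overall) and 1,000 randomized
round-trip datasets — comfortably representative for a tool whose real
inputs are files of a few hundred candidate SNPs, while keeping the full
suite around ten seconds.

## Known limitations

* Only human-style chromosome labels (1–22, X, Y, MT) are accepted.
* No genome-wide joint analysis; every operation is per-chromosome.
* The `total` depth dialect supports presence/absence comparison only.
* VCF import takes the first sample's AD field for counts; without AD,
  counts are unavailable.
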