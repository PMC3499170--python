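# snptrack

Post-processing and visualization support for SNP calls from deep-sequencing
experiments. When a study resequences several individuals from an affected
family or population, the upstream pipeline (alignment with MAQ or similar,
then SNP calling) leaves each sample as a plain-text list of candidate SNPs
— often hundreds of lines — and the researcher's next task is ranking them:
which variants are shared by the affected samples, which are heterozygous or
homozygous, and what do they look like in a genome browser. `snptrack` is a
scriptable library and command-line tool for exactly that step.

It works on a simple tab-separated, headerless format, one sample per file,
with fixed leading columns

```
chromosome  position  consensus_nt  snp_nt  score  <read counts>  [annotations...]
```

where position is 1-based, a score of `0` means "missing", and the read-count
columns come in one of three layouts (four per-nucleotide counts in A,C,G,T
order — the default; a consensus/SNP pair; or a single total depth), selected
explicitly or auto-sniffed. VCF import is available as a convenience.

## What it computes

* **Mutant-read fraction and zygosity.** For a call with per-nucleotide read
  counts *n*<sub>A..T</sub> and SNP nucleotide *b*, the mutant-read fraction
  is *f* = *n*<sub>b</sub> / Σ*n*. Under a diploid model *f* ≈ 0.5 indicates
  heterozygosity and *f* ≈ 1 homozygosity for the variant; calls are labelled
  `het` for *f* ∈ [0.2, 0.8), `hom_alt` for *f* ≥ 0.8, `ambiguous_low` below
  (band configurable).
* **Data table** — all input columns plus mutant-read percentage and
  zygosity, per chromosome, exported as TSV/CSV for spreadsheet work.
* **Sample comparison** — for each SNP key (chromosome, position, SNP
  nucleotide), its frequency of appearance *k*/*N* across the *N* selected
  samples, with an inclusive user threshold selecting the surviving set, bar-
  chart data and an index table.
* **SNP view** — the SNP × sample presence matrix for a chromosome, with the
  list of samples carrying each SNP.
* **pgSnp export** — conversion to UCSC Genome Browser `pgSnp` custom-track
  lines (0-based half-open coordinates, observed alleles with per-allele read
  counts and scores) for display alongside the browser's annotation tracks.

A deterministic synthetic-cohort generator (`snptrack.fixtures`) produces
native-format files with known sharing structure, zygosity labels and depth,
so the whole pipeline is testable without any external data.

## Worked example

The built-in three-sample toy cohort (`snptrack.worked_example()`) contains
five SNPs on chromosome 1; one (`1:1000 A>G`) is carried by all three
samples, one by two of the three, and three are private.

```python
import snptrack as st

trio = st.worked_example()
report = st.compare_samples(trio, chrom="1", threshold=0.5)
for e in report.entries:
    print(e.key, e.count, f"{e.frequency:.3f}", ",".join(e.samples))
```

prints

```
1:1000G 3 1.000 S1,S2,S3
1:2000T 2 0.667 S1,S2
1:3000A 1 0.333 S1
1:4000C 1 0.333 S2
1:5000C 1 0.333 S3
```

so with threshold 0.5 the surviving set is `1:1000G` (frequency 1.0) and
`1:2000T` (0.667) — the candidates shared by most samples. The same cohort
exported as a custom track (`st.write_pgsnp_track(trio[0], "S1.pgsnp")`)
yields

```
track type=pgSnp visibility=3 name="S1" description="SNP calls"
chr1	999	1000	A/G	2	10,10	50,50
chr1	1999	2000	C/T	2	12,8	60,60
chr1	2999	3000	G/A	2	2,18	40,40
chr2	99	100	G	1	15	70
```

— e.g. the first line is a heterozygous A/G site (10 reads each) at 1-based
position 1000, ready to upload to the UCSC browser.

The same operations are available from the shell:

```
snptrack compare --chrom 1 --threshold 0.5 -i s1.txt:S1 -i s2.txt:S2 -i s3.txt:S3 -o out/
snptrack table --chrom 1 -i s1.txt:S1 -o out/
snptrack pgsnp -i s1.txt:S1 -o out/
snptrack info          # external resources for follow-up annotation
snptrack generate --n-samples 5 --n-snps 200 --seed 7 -o cohort/
```

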