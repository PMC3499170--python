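"""Deterministic synthetic SNP-call data with known ground truth.

Emulates the situation the comparison tools target: several samples from a
related or affected population, each sequenced and SNP-called upstream, with
some variants shared by every sample, some private to one, and the rest
carried by random subsets.  Read counts follow a simple diploid model —
depth Poisson around ``depth_mean``, the mutant-allele share binomial (p=0.5
for heterozygous carriers, 1-error for homozygous-alternate) with per-read
miscalls scattered uniformly over the other nucleotides.  The generator
returns the ground truth (who carries what, and with which zygosity) so
recovery can be checked exactly.

Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import (
    NUCLEOTIDES,
    Category,
    SampleDataset,
    SnpKey,
    SnpRecord,
    chrom_sort_key,
)
from .snp_io import write_snp_file

__all__ = ["FixtureSpec", "TruthEntry", "generate", "write_fixture", "worked_example"]

_POS_MAX = 10_000_000  # positions drawn uniquely per chromosome from [1, _POS_MAX]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cohort.

    Defaults model a small resequencing study: five samples, 200 SNPs over
    two chromosomes, 30x mean depth, 1% per-read miscall rate, half the
    carrier calls heterozygous, 30% of SNPs shared by everyone and 30%
    private to one sample (the remainder land in random subsets).
    """

    n_samples: int = 5
    n_snps: int = 200
    chroms: tuple[str, ...] = ("1", "2")
    shared_fraction: float = 0.3
    private_fraction: float = 0.3
    het_fraction: float = 0.5
    depth_mean: float = 30.0
    error_rate: float = 0.01
    missing_score_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples and n_snps must be >= 1")
        for name in ("shared_fraction", "private_fraction", "het_fraction",
                     "missing_score_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.shared_fraction + self.private_fraction > 1.0 + 1e-12:
            raise ValueError("shared_fraction + private_fraction must be <= 1")
        if not self.chroms:
            raise ValueError("need at least one chromosome")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not (0.0 <= self.error_rate <= 0.25):
            raise ValueError("error_rate must be in [0, 0.25]")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one synthetic SNP."""

    key: SnpKey
    ref: str
    carriers: tuple[str, ...]  # sample ids, sorted
    zygosity: dict[str, str] = field(hash=False, default_factory=dict)  # sample -> het|hom_alt


def _unique_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    """n distinct positions in [1, _POS_MAX], sorted; rejection-sampled so the
    cost stays O(n) even though the position space is huge."""
    pool = np.unique(rng.integers(1, _POS_MAX + 1, size=2 * n + 16))
    while len(pool) < n:
        extra = rng.integers(1, _POS_MAX + 1, size=2 * n + 16)
        pool = np.unique(np.concatenate([pool, extra]))
    return pool[:n]


def _draw_counts(
    rng: np.random.Generator, ref: str, alt: str, het: bool, spec: FixtureSpec
) -> dict[str, int]:
    depth = int(rng.poisson(spec.depth_mean))
    counts = {nt: 0 for nt in NUCLEOTIDES}
    if depth == 0:
        return counts
    n_alt_true = int(rng.binomial(depth, 0.5)) if het else depth
    for true_allele, n in ((alt, n_alt_true), (ref, depth - n_alt_true)):
        n_err = int(rng.binomial(n, spec.error_rate)) if spec.error_rate > 0 else 0
        counts[true_allele] += n - n_err
        if n_err:
            others = [nt for nt in NUCLEOTIDES if nt != true_allele]
            for idx in rng.integers(0, 3, size=n_err):
                counts[others[idx]] += 1
    return counts


def generate(spec: FixtureSpec) -> tuple[list[SampleDataset], dict[SnpKey, TruthEntry]]:
    """Draw one synthetic cohort; return the datasets and the truth table.

    Sharing sets are exact: ``round(shared_fraction * n_snps)`` SNPs appear
    in every sample and ``round(private_fraction * n_snps)`` in exactly one;
    the rest go to uniform random subsets of size 2..n_samples-1 (degenerate
    sample counts collapse those sizes sensibly).  Positions are unique per
    chromosome, so presence counting over the output is noise-free.
    """
    rng = np.random.default_rng(spec.seed)
    # distribute SNPs over chromosomes as evenly as possible
    base, rem = divmod(spec.n_snps, len(spec.chroms))
    n_per_chrom = [base + (1 if i < rem else 0) for i in range(len(spec.chroms))]
    if max(n_per_chrom) > _POS_MAX:
        raise ValueError("n_snps exceeds the available unique positions per chromosome")

    sample_ids = [f"S{i + 1}" for i in range(spec.n_samples)]
    sites: list[tuple[str, int, str, str]] = []  # chrom, pos, ref, alt
    for chrom, n in zip(spec.chroms, n_per_chrom):
        positions = _unique_positions(rng, n)
        for pos in positions:
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
            sites.append((chrom, int(pos), NUCLEOTIDES[ref_i], NUCLEOTIDES[alt_i]))

    n_shared = round(spec.shared_fraction * spec.n_snps)
    n_private = round(spec.private_fraction * spec.n_snps)
    order = rng.permutation(spec.n_snps)
    shared_idx = set(order[:n_shared].tolist())
    private_idx = set(order[n_shared : n_shared + n_private].tolist())

    truth: dict[SnpKey, TruthEntry] = {}
    per_sample_records: dict[str, list[SnpRecord]] = {s: [] for s in sample_ids}
    for i, (chrom, pos, ref, alt) in enumerate(sites):
        if i in shared_idx or spec.n_samples == 1:
            carriers = list(sample_ids)
        elif i in private_idx:
            carriers = [sample_ids[int(rng.integers(0, spec.n_samples))]]
        else:
            # random subset of intermediate size; with 2 samples that means both
            lo, hi = (2, spec.n_samples - 1) if spec.n_samples > 3 else (2, 2)
            hi = max(lo, min(hi, spec.n_samples))
            size = int(rng.integers(lo, hi + 1))
            size = min(size, spec.n_samples)
            carriers = [sample_ids[j] for j in sorted(
                rng.choice(spec.n_samples, size=size, replace=False).tolist()
            )]
        zygosity: dict[str, str] = {}
        for s in carriers:
            het = bool(rng.random() < spec.het_fraction)
            zygosity[s] = "het" if het else "hom_alt"
            counts = _draw_counts(rng, ref, alt, het, spec)
            score = 0.0 if rng.random() < spec.missing_score_fraction \
                else float(rng.integers(20, 91))
            per_sample_records[s].append(
                SnpRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                          score=score, counts=counts)
            )
        key = SnpKey(chrom_sort_key(chrom), pos, alt)
        truth[key] = TruthEntry(key=key, ref=ref, carriers=tuple(sorted(carriers)),
                                zygosity=zygosity)

    datasets = [
        SampleDataset(sample_id=s, records=per_sample_records[s],
                      category=Category.UNSPECIFIED, source="synthetic")
        for s in sample_ids
    ]
    return datasets, truth


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Write the cohort as native-format files plus a ``truth.tsv`` table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets, truth = generate(spec)
    paths = []
    for ds in datasets:
        p = out_dir / f"{ds.sample_id}.txt"
        write_snp_file(ds, p)
        paths.append(p)
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("chrom\tpos\tref\talt\tcarriers\tzygosity\n")
        for key in sorted(truth):
            t = truth[key]
            zyg = ",".join(f"{s}:{t.zygosity[s]}" for s in t.carriers)
            fh.write(f"{key.chrom}\t{key.pos}\t{t.ref}\t{key.alt}\t"
                     f"{','.join(t.carriers)}\t{zyg}\n")
    paths.append(truth_path)
    return paths


def worked_example() -> list[SampleDataset]:
    """A fixed three-sample toy cohort with hand-computable results.

    On chromosome 1 (three samples S1, S2, S3):

    * ``1:1000 A>G`` — carried by all three samples (frequency 1.0);
      heterozygous in S1 (10/20 mutant reads) and S3 (11/20), homozygous in
      S2 (20/20).  S3's call has score 0, i.e. missing.
    * ``1:2000 C>T`` — carried by S1 and S2 (frequency 2/3).
    * ``1:3000 G>A`` (S1), ``1:4000 T>C`` (S2), ``1:5000 A>C`` (S3) —
      private (frequency 1/3 each).

    S1 additionally carries ``2:100 C>G`` on chromosome 2 with annotation
    extras, exercising chromosome filtering and extra columns.
    """
    s1 = SampleDataset(
        sample_id="S1",
        category=Category.NOVEL,
        records=[
            SnpRecord("1", 1000, "A", "G", 50, {"A": 10, "C": 0, "G": 10, "T": 0}),
            SnpRecord("1", 2000, "C", "T", 60, {"A": 0, "C": 12, "G": 0, "T": 8}),
            SnpRecord("1", 3000, "G", "A", 40, {"A": 18, "C": 0, "G": 2, "T": 0}),
            SnpRecord("2", 100, "C", "G", 70, {"A": 0, "C": 0, "G": 15, "T": 0},
                      extras=["BRCA1", "novel"]),
        ],
    )
    s2 = SampleDataset(
        sample_id="S2",
        category=Category.NOVEL,
        records=[
            SnpRecord("1", 1000, "A", "G", 55, {"A": 0, "C": 0, "G": 20, "T": 0}),
            SnpRecord("1", 2000, "C", "T", 45, {"A": 0, "C": 10, "G": 0, "T": 10}),
            SnpRecord("1", 4000, "T", "C", 35, {"A": 0, "C": 22, "G": 0, "T": 0}),
        ],
    )
    s3 = SampleDataset(
        sample_id="S3",
        category=Category.CLINICAL,
        records=[
            SnpRecord("1", 1000, "A", "G", 0, {"A": 9, "C": 0, "G": 11, "T": 0}),
            SnpRecord("1", 5000, "A", "C", 65, {"A": 5, "C": 15, "G": 0, "T": 0}),
        ],
    )
    return [s1, s2, s3]
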