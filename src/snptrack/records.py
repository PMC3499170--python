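"""Core domain types shared by every module.

The unit of data is a single SNP call: one substitution relative to the
consensus (reference) sequence, with a call score and per-nucleotide read
counts.  Calls are grouped into per-sample datasets; across samples a call
is identified by its (chromosome, position, alternate allele) key.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator

NUCLEOTIDES = ("A", "C", "G", "T")
ALLOWED_ALLELES = frozenset(NUCLEOTIDES) | {"N"}

#: Canonical chromosome ordering: autosomes 1-22, then X, Y, MT.
CHROM_ORDER: dict[str, int] = {str(i): i for i in range(1, 23)}
CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25})


class ChromosomeError(ValueError):
    """Raised for a chromosome token outside the accepted human set."""


def normalize_chrom(token: str) -> str:
    """Normalize a chromosome label to its prefix-free canonical form.

    Accepts ``1``..``22``, ``X``, ``Y``, ``MT`` with or without a ``chr``
    prefix; ``M`` and ``MT`` both map to ``MT``.
    """
    t = token.strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    t = t.upper()
    if t == "M":
        t = "MT"
    if t not in CHROM_ORDER:
        raise ChromosomeError(f"unrecognized chromosome label: {token!r}")
    return t


def chrom_sort_key(chrom: str) -> int:
    return CHROM_ORDER[chrom]


def ucsc_chrom(chrom: str) -> str:
    """UCSC-style name: ``chr`` prefix, mitochondrial ``MT`` -> ``chrM``."""
    return "chrM" if chrom == "MT" else f"chr{chrom}"


class Category(str, enum.Enum):
    """Whether a sample file holds novel or clinically associated SNPs."""

    NOVEL = "novel"
    CLINICAL = "clinical"
    UNSPECIFIED = "unspecified"


class CountsLayout(str, enum.Enum):
    """Interpretation of the read-count columns of the native format.

    ``four_nt``
        four columns, one count per nucleotide in A, C, G, T order
    ``ref_alt``
        two columns: reads supporting the consensus, reads supporting the SNP
    ``total``
        a single total-depth column; per-allele counts are unrecoverable
    """

    FOUR_NT = "four_nt"
    REF_ALT = "ref_alt"
    TOTAL = "total"

    @property
    def n_count_columns(self) -> int:
        return {CountsLayout.FOUR_NT: 4, CountsLayout.REF_ALT: 2, CountsLayout.TOTAL: 1}[self]


@dataclass(frozen=True)
class FormatDialect:
    """Concrete column layout of a native SNP-call file."""

    counts_layout: CountsLayout = CountsLayout.FOUR_NT

    @property
    def column_offset(self) -> int:
        """0-based index of the first optional (extras) column."""
        return 5 + self.counts_layout.n_count_columns


FOUR_NT = FormatDialect(CountsLayout.FOUR_NT)
REF_ALT = FormatDialect(CountsLayout.REF_ALT)
TOTAL = FormatDialect(CountsLayout.TOTAL)


@dataclass(frozen=True, order=True)
class SnpKey:
    """Identity of a SNP across samples: (chromosome rank, position, alt)."""

    chrom_rank: int
    pos: int
    alt: str

    @property
    def chrom(self) -> str:
        for name, rank in CHROM_ORDER.items():
            if rank == self.chrom_rank:
                return name
        raise ChromosomeError(f"invalid chromosome rank {self.chrom_rank}")

    @classmethod
    def make(cls, chrom: str, pos: int, alt: str) -> "SnpKey":
        return cls(chrom_sort_key(normalize_chrom(chrom)), pos, alt)

    def __str__(self) -> str:  # e.g. "1:10583G"
        return f"{self.chrom}:{self.pos}{self.alt}"


@dataclass
class SnpRecord:
    """One SNP call.

    ``score == 0`` encodes a missing score (the native format's rule for any
    absent value); it is carried as-is, never imputed.  ``counts_exact`` is
    False when the source carried only a total depth, in which case the whole
    depth sits under ``alt`` and per-allele quantities are unavailable.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    score: float
    counts: dict[str, int]
    extras: list[str] = field(default_factory=list)
    counts_exact: bool = True

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in ALLOWED_ALLELES or self.alt not in ALLOWED_ALLELES:
            raise ValueError(f"invalid alleles {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        self.score = float(self.score)
        if self.score < 0:
            raise ValueError(f"negative score {self.score}")
        self.counts = {nt: int(self.counts.get(nt, 0)) for nt in NUCLEOTIDES}
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")
        self.extras = [str(x) for x in self.extras]

    @property
    def key(self) -> SnpKey:
        return SnpKey(chrom_sort_key(self.chrom), self.pos, self.alt)

    @property
    def score_is_missing(self) -> bool:
        return self.score == 0

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def sort_key(self) -> tuple[int, int, str]:
        return (chrom_sort_key(self.chrom), self.pos, self.alt)


@dataclass
class SampleDataset:
    """All SNP calls of one sample, plus file-level metadata.

    Records are kept sorted by (chromosome, position, alt) and unique on
    (chromosome, position, alt).
    """

    sample_id: str
    records: list[SnpRecord] = field(default_factory=list)
    category: Category = Category.UNSPECIFIED
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.sample_id = str(self.sample_id)
        self.records = sorted(self.records, key=SnpRecord.sort_key)
        seen: set[SnpKey] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(f"duplicate SNP key {rec.key} in sample {self.sample_id}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    @property
    def keys(self) -> set[SnpKey]:
        return {rec.key for rec in self.records}

    def chromosomes(self) -> list[str]:
        """Distinct chromosomes present, in canonical order."""
        return sorted({rec.chrom for rec in self.records}, key=chrom_sort_key)

    def on_chrom(self, chrom: str) -> list[SnpRecord]:
        c = normalize_chrom(chrom)
        return [rec for rec in self.records if rec.chrom == c]


def union_keys(datasets: Iterable[SampleDataset], chrom: str | None = None) -> list[SnpKey]:
    """Sorted union of SNP keys over datasets, optionally restricted to one chromosome."""
    keys: set[SnpKey] = set()
    for ds in datasets:
        if chrom is None:
            keys |= ds.keys
        else:
            keys |= {rec.key for rec in ds.on_chrom(chrom)}
    return sorted(keys)
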