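"""Conversion of SNP calls to UCSC pgSnp (Personal Genome SNP) custom tracks.

pgSnp extends BED with allele information: each line is
``chrom chromStart chromEnd name alleleCount alleleFreq alleleScores`` where
``name`` joins the observed alleles with ``/``, ``alleleFreq`` carries the
per-allele observed read counts and ``alleleScores`` a per-allele quality
score, both comma-joined in the same order as ``name``.  Coordinates are
0-based half-open, so a SNP at 1-based position p occupies [p-1, p).

The upstream format carries a single score per call, not per allele; the
writer replicates that score across the emitted alleles, which is lossless
and explicit.  Alleles with zero supporting reads are omitted by default so
a homozygous-alternate call renders as a single allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .records import (
    NUCLEOTIDES,
    SampleDataset,
    SnpRecord,
    chrom_sort_key,
    normalize_chrom,
    ucsc_chrom,
)

__all__ = [
    "PgSnpError",
    "UnavailableCountsError",
    "PgSnpRecord",
    "to_pgsnp_record",
    "write_pgsnp_track",
    "parse_pgsnp",
    "write_bed4",
]

TRACK_TEMPLATE = 'track type=pgSnp visibility=3 name="{name}" description="{description}"'


class PgSnpError(ValueError):
    """Base class for pgSnp construction/parsing failures."""


class UnavailableCountsError(PgSnpError):
    """The source record has no per-allele read counts (total-depth dialect)."""


@dataclass(frozen=True)
class PgSnpRecord:
    """One pgSnp custom-track line."""

    chrom: str  # UCSC-style, "chr" prefix
    chromStart: int  # 0-based inclusive
    chromEnd: int  # exclusive; chromStart + 1 for a SNP
    name: str  # alleles joined by "/"
    alleleCount: int
    alleleFreq: str  # comma-joined read counts, same order as name
    alleleScores: str  # comma-joined scores, same order as name

    def __post_init__(self) -> None:
        if self.chromStart < 0:
            raise PgSnpError(f"negative chromStart {self.chromStart}")
        if self.chromEnd - self.chromStart != 1:
            raise PgSnpError(
                f"SNP interval must have length 1, got [{self.chromStart}, {self.chromEnd})"
            )
        alleles = self.name.split("/")
        freqs = self.alleleFreq.split(",")
        scores = self.alleleScores.split(",")
        if not (len(alleles) == len(freqs) == len(scores) == self.alleleCount):
            raise PgSnpError(
                f"token arity mismatch: name={self.name!r} freq={self.alleleFreq!r} "
                f"scores={self.alleleScores!r} alleleCount={self.alleleCount}"
            )

    @property
    def alleles(self) -> list[str]:
        return self.name.split("/")

    def to_line(self) -> str:
        return "\t".join(
            [
                self.chrom,
                str(self.chromStart),
                str(self.chromEnd),
                self.name,
                str(self.alleleCount),
                self.alleleFreq,
                self.alleleScores,
            ]
        )


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


def to_pgsnp_record(
    record: SnpRecord,
    *,
    keep_zero_alleles: bool = False,
    include_third_allele: bool = False,
) -> PgSnpRecord:
    """Map one SNP call to a pgSnp line.

    The allele list is built ref-first: consensus allele (when it carries
    reads, or always under ``keep_zero_alleles``), then the SNP allele, then
    — only under ``include_third_allele`` — any other nucleotide with reads.
    Reads on a third allele are otherwise dropped with a warning, since the
    upstream format has no slot for them.
    """
    if not record.counts_exact:
        raise UnavailableCountsError(
            f"{record.chrom}:{record.pos}: per-allele counts unavailable"
        )
    alleles: list[str] = []
    for nt in (record.ref, record.alt):
        if keep_zero_alleles or record.counts.get(nt, 0) > 0:
            alleles.append(nt)
    if not alleles:  # zero-depth record: emit the alt allele alone
        alleles = [record.alt]
    third = [
        nt for nt in NUCLEOTIDES
        if nt not in (record.ref, record.alt) and record.counts[nt] > 0
    ]
    if third:
        if include_third_allele:
            alleles.extend(third)
        else:
            warnings.warn(
                f"{record.chrom}:{record.pos}: ignoring reads on third allele(s) "
                f"{','.join(third)}",
                stacklevel=2,
            )
    score = _format_score(record.score)
    return PgSnpRecord(
        chrom=ucsc_chrom(record.chrom),
        chromStart=record.pos - 1,
        chromEnd=record.pos,
        name="/".join(alleles),
        alleleCount=len(alleles),
        alleleFreq=",".join(str(record.counts[a]) for a in alleles),
        alleleScores=",".join(score for _ in alleles),
    )


def write_pgsnp_track(
    dataset: SampleDataset,
    path: str | Path,
    *,
    track_name: str | None = None,
    description: str = "SNP calls",
    chrom_filter: str | None = None,
    keep_zero_alleles: bool = False,
    include_third_allele: bool = False,
) -> int:
    """Write a dataset as a pgSnp custom-track file; return the skip count.

    The first line is the ``track type=pgSnp`` header; records follow sorted
    by (chromosome, chromStart).  Records whose counts cannot be expressed
    per-allele are skipped and counted, never silently dropped.
    """
    records = (
        dataset.records
        if chrom_filter is None
        else dataset.on_chrom(normalize_chrom(chrom_filter))
    )
    converted: list[PgSnpRecord] = []
    skipped = 0
    for rec in records:
        try:
            converted.append(
                to_pgsnp_record(
                    rec,
                    keep_zero_alleles=keep_zero_alleles,
                    include_third_allele=include_third_allele,
                )
            )
        except UnavailableCountsError:
            skipped += 1
    converted.sort(key=lambda r: (chrom_sort_key(normalize_chrom(r.chrom)), r.chromStart))
    header = TRACK_TEMPLATE.format(
        name=track_name if track_name is not None else dataset.sample_id,
        description=description,
    )
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for rec in converted:
            fh.write(rec.to_line() + "\n")
    return skipped


def parse_pgsnp(path: str | Path) -> tuple[str | None, list[PgSnpRecord]]:
    """Parse a pgSnp custom-track file, checking every line's invariants.

    Returns the track header line (or None) and the records.  Raises
    :class:`PgSnpError` with a line number on any field-count or invariant
    violation.
    """
    track_line: str | None = None
    records: list[PgSnpRecord] = []
    with open(Path(path), "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("track "):
                track_line = line
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise PgSnpError(f"line {line_no}: expected 7 fields, got {len(fields)}")
            try:
                rec = PgSnpRecord(
                    chrom=fields[0],
                    chromStart=int(fields[1]),
                    chromEnd=int(fields[2]),
                    name=fields[3],
                    alleleCount=int(fields[4]),
                    alleleFreq=fields[5],
                    alleleScores=fields[6],
                )
            except (ValueError, PgSnpError) as exc:
                raise PgSnpError(f"line {line_no}: {exc}") from exc
            records.append(rec)
    return track_line, records


def write_bed4(dataset: SampleDataset, path: str | Path, *, track_name: str | None = None) -> None:
    """Degraded fallback: plain BED4 (chrom, start, end, ref>alt name)."""
    name = track_name if track_name is not None else dataset.sample_id
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f'track name="{name}"\n')
        for rec in dataset.records:
            fh.write(
                f"{ucsc_chrom(rec.chrom)}\t{rec.pos - 1}\t{rec.pos}\t{rec.ref}>{rec.alt}\n"
            )
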