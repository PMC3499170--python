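"""Reader and writer for the native tab-separated SNP-call format.

The native format is a headerless ``.txt`` file, one SNP call per line,
tab-separated, columns in fixed order: chromosome, 1-based position,
consensus nucleotide, SNP nucleotide, call score, then the read-count
columns, then any optional annotation columns (gene name, novel/known flag,
CDS flag, synonymy, amino-acid change, SNP id, ...).  A ``0`` in the score
column means the score is missing.

Because upstream SNP callers of the MAQ era disagreed on how "number of
reads of each nucleotide" was laid out, the count columns are interpreted
through an explicit :class:`~snptrack.records.FormatDialect` (four
per-nucleotide counts, a ref/alt pair, or a single total), with a sniffer
for files of unknown provenance.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable

from .records import (
    ALLOWED_ALLELES,
    NUCLEOTIDES,
    Category,
    ChromosomeError,
    CountsLayout,
    FormatDialect,
    SampleDataset,
    SnpKey,
    SnpRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SnpFormatError",
    "MalformedLineError",
    "EmptyFileError",
    "DuplicateKeyError",
    "UndecidableDialectError",
    "parse_snp_file",
    "parse_snp_lines",
    "write_snp_file",
    "format_record",
    "sniff_dialect",
    "import_vcf",
]


class SnpFormatError(ValueError):
    """Base class for native-format violations."""


class MalformedLineError(SnpFormatError):
    def __init__(self, line_no: int, reason: str, line: str = ""):
        self.line_no = line_no
        self.reason = reason
        super().__init__(f"line {line_no}: {reason}" + (f" [{line!r}]" if line else ""))


class EmptyFileError(SnpFormatError):
    pass


class DuplicateKeyError(SnpFormatError):
    def __init__(self, line_no: int, key: SnpKey):
        self.line_no = line_no
        self.key = key
        super().__init__(f"line {line_no}: duplicate SNP key {key}")


class UndecidableDialectError(SnpFormatError):
    pass


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def _parse_line(fields: list[str], dialect: FormatDialect, line_no: int) -> SnpRecord:
    n_counts = dialect.counts_layout.n_count_columns
    if len(fields) < 5 + n_counts:
        raise MalformedLineError(
            line_no,
            f"expected at least {5 + n_counts} tab-separated fields "
            f"for dialect {dialect.counts_layout.value}, got {len(fields)}",
        )
    try:
        chrom = normalize_chrom(fields[0])
    except ChromosomeError as exc:
        raise MalformedLineError(line_no, str(exc)) from exc
    if not _is_int(fields[1]):
        raise MalformedLineError(line_no, f"non-integer position {fields[1]!r}")
    pos = int(fields[1])
    if pos < 1:
        raise MalformedLineError(line_no, f"position must be >= 1, got {pos}")
    ref, alt = fields[2].upper(), fields[3].upper()
    for label, allele in (("consensus", ref), ("SNP", alt)):
        if allele not in ALLOWED_ALLELES:
            raise MalformedLineError(line_no, f"invalid {label} nucleotide {allele!r}")
    if ref == alt:
        raise MalformedLineError(line_no, f"consensus and SNP nucleotide both {ref!r}")
    try:
        score = float(fields[4])
    except ValueError:
        raise MalformedLineError(line_no, f"non-numeric score {fields[4]!r}") from None
    if score < 0:
        raise MalformedLineError(line_no, f"negative score {score}")

    raw_counts = fields[5 : 5 + n_counts]
    for tok in raw_counts:
        if not _is_int(tok) or int(tok) < 0:
            raise MalformedLineError(line_no, f"invalid read count {tok!r}")
    values = [int(t) for t in raw_counts]
    counts_exact = True
    if dialect.counts_layout is CountsLayout.FOUR_NT:
        counts = dict(zip(NUCLEOTIDES, values))
    elif dialect.counts_layout is CountsLayout.REF_ALT:
        counts = {nt: 0 for nt in NUCLEOTIDES}
        counts[ref], counts[alt] = values[0], values[1]
    else:  # TOTAL: whole depth under alt; per-allele quantities unavailable
        counts = {nt: 0 for nt in NUCLEOTIDES}
        counts[alt] = values[0]
        counts_exact = False

    extras = [f.strip() for f in fields[5 + n_counts :]]
    return SnpRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, score=score,
        counts=counts, extras=extras, counts_exact=counts_exact,
    )


def parse_snp_lines(
    lines: Iterable[str],
    dialect: FormatDialect = FormatDialect(),
    *,
    sample_id: str = "sample",
    category: Category = Category.UNSPECIFIED,
    source: str = "<memory>",
    strict_duplicates: bool = False,
) -> SampleDataset:
    """Parse native-format lines into a :class:`SampleDataset`.

    Every non-blank line either yields exactly one record or raises a
    diagnosed error carrying its line number.  Duplicate (chrom, pos, alt)
    keys keep the first occurrence with a warning, or raise
    :class:`DuplicateKeyError` under ``strict_duplicates``.
    """
    records: dict[SnpKey, SnpRecord] = {}
    n_lines = 0
    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        n_lines += 1
        rec = _parse_line(line.split("\t"), dialect, line_no)
        if rec.key in records:
            if strict_duplicates:
                raise DuplicateKeyError(line_no, rec.key)
            warnings.warn(
                f"{source}: line {line_no}: duplicate SNP key {rec.key}; keeping first",
                stacklevel=2,
            )
            continue
        records[rec.key] = rec
    if n_lines == 0:
        raise EmptyFileError(f"{source}: no data lines")
    return SampleDataset(
        sample_id=sample_id,
        records=list(records.values()),
        category=category,
        source=source,
    )


def parse_snp_file(
    path: str | Path,
    dialect: FormatDialect | None = None,
    *,
    sample_id: str | None = None,
    category: Category = Category.UNSPECIFIED,
    strict_duplicates: bool = False,
) -> SampleDataset:
    """Read one sample's SNP-call file.

    ``dialect=None`` sniffs the count-column layout from the file itself.
    ``sample_id`` defaults to the file stem.
    """
    path = Path(path)
    if dialect is None:
        dialect = sniff_dialect(path)
    with open(path, "r", encoding="utf-8") as fh:
        return parse_snp_lines(
            fh,
            dialect,
            sample_id=sample_id if sample_id is not None else path.stem,
            category=category,
            source=str(path),
            strict_duplicates=strict_duplicates,
        )


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


def format_record(rec: SnpRecord, dialect: FormatDialect = FormatDialect()) -> str:
    """Serialize one record to a native-format line (no newline)."""
    fields = [rec.chrom, str(rec.pos), rec.ref, rec.alt, _format_score(rec.score)]
    layout = dialect.counts_layout
    if layout is CountsLayout.FOUR_NT:
        fields += [str(rec.counts[nt]) for nt in NUCLEOTIDES]
    elif layout is CountsLayout.REF_ALT:
        fields += [str(rec.counts[rec.ref]), str(rec.counts[rec.alt])]
    else:
        fields.append(str(rec.total_reads))
    fields += rec.extras
    return "\t".join(fields)


def write_snp_file(
    dataset: SampleDataset,
    path: str | Path,
    dialect: FormatDialect = FormatDialect(),
) -> None:
    """Write a dataset in the native format (headerless, tab-separated).

    With the ``four_nt`` dialect the writer and :func:`parse_snp_file` are
    exact inverses record-for-record.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in dataset.records:
            fh.write(format_record(rec, dialect) + "\n")


def sniff_dialect(path: str | Path) -> FormatDialect:
    """Infer the count-column layout from the first data line.

    Counts the run of integer-valued columns immediately after the score
    column; ambiguity resolves four_nt > ref_alt > total.  Deterministic for
    a fixed file.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = next((ln.rstrip("\r\n") for ln in fh if ln.strip()), None)
    if first is None:
        raise EmptyFileError(f"{path}: no data lines")
    fields = first.split("\t")
    if len(fields) < 6:
        raise UndecidableDialectError(
            f"{path}: only {len(fields)} columns; every layout needs at least 6"
        )
    run = 0
    for tok in fields[5:]:
        if _is_int(tok) and int(tok) >= 0:
            run += 1
        else:
            break
    if run >= 4:
        return FormatDialect(CountsLayout.FOUR_NT)
    if run >= 2:
        return FormatDialect(CountsLayout.REF_ALT)
    if run >= 1:
        return FormatDialect(CountsLayout.TOTAL)
    raise UndecidableDialectError(
        f"{path}: column 6 ({fields[5]!r}) is not a non-negative integer"
    )


def import_vcf(
    path: str | Path,
    sample_id: str | None = None,
    *,
    category: Category = Category.UNSPECIFIED,
) -> tuple[SampleDataset, int]:
    """Import SNVs from a VCF file as a convenience entry point.

    Maps CHROM/POS/REF/ALT/QUAL onto the native fields; the per-sample AD
    (allelic depth) field, when present, fills the ref/alt read counts.
    Multi-allelic records are split into one record per alternate allele.
    Indels and other non-SNV alleles are skipped, not errors; the second
    return value is the skip count.
    """
    import pysam  # optional dependency, only needed for VCF import

    path = Path(path)
    records: list[SnpRecord] = []
    seen: set[SnpKey] = set()
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for var in vcf:
            ref = (var.ref or "").upper()
            ad = None
            if sample_names:
                ad = var.samples[sample_names[0]].get("AD")
            for i, alt in enumerate(var.alts or ()):
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in ALLOWED_ALLELES or alt not in ALLOWED_ALLELES or ref == alt:
                    skipped += 1
                    continue
                try:
                    chrom = normalize_chrom(var.chrom)
                except ChromosomeError:
                    skipped += 1
                    continue
                counts = {nt: 0 for nt in NUCLEOTIDES}
                counts_exact = False
                if ad is not None and len(ad) > i + 1 and ad[0] is not None and ad[i + 1] is not None:
                    counts[ref] = int(ad[0])
                    counts[alt] = int(ad[i + 1])
                    counts_exact = True
                rec = SnpRecord(
                    chrom=chrom,
                    pos=var.pos,
                    ref=ref,
                    alt=alt,
                    score=float(var.qual) if var.qual is not None else 0.0,
                    counts=counts,
                    counts_exact=counts_exact,
                )
                if rec.key in seen:
                    skipped += 1
                    continue
                seen.add(rec.key)
                records.append(rec)
    if skipped:
        logger.info("%s: skipped %d non-SNV or duplicate alleles", path, skipped)
    dataset = SampleDataset(
        sample_id=sample_id if sample_id is not None else path.stem,
        records=records,
        category=category,
        source=str(path),
    )
    return dataset, skipped
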