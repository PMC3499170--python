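"""Per-chromosome SNP analysis: data table, sample comparison, SNP view.

Three operations mirror the workflow a researcher applies to per-sample SNP
lists when hunting a disease-causing mutation:

* :func:`build_data_table` — everything the input files carry, plus the
  percentage of mutant reads and a zygosity call, per chromosome.
* :func:`compare_samples` — for every SNP on a chromosome, the fraction of
  samples carrying it, filtered by a user threshold.  A SNP shared by most
  affected samples is a stronger candidate than a private one.
* :func:`snp_view` — the SNP x sample presence matrix with, per SNP, the
  list of samples containing it.

A SNP is identified across samples by (chromosome, position, alternate
allele); an optional position-only mode relaxes the identity to
(chromosome, position).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import (
    NUCLEOTIDES,
    SampleDataset,
    SnpKey,
    SnpRecord,
    normalize_chrom,
)

__all__ = [
    "Zygosity",
    "ZygosityCall",
    "FrequencyEntry",
    "FrequencyReport",
    "PresenceMatrix",
    "DEFAULT_HET_BAND",
    "mutant_read_fraction",
    "classify_zygosity",
    "build_data_table",
    "compare_samples",
    "snp_view",
    "export_table",
]

#: Default heterozygosity band on the mutant-read fraction: calls with a
#: fraction in [0.2, 0.8) are heterozygous, >= 0.8 homozygous-alternate,
#: < 0.2 too few mutant reads to call.  Conventional diploid heuristic.
DEFAULT_HET_BAND: tuple[float, float] = (0.2, 0.8)


def mutant_read_fraction(record: SnpRecord) -> float | None:
    """Fraction of reads supporting the alternate allele, or None.

    None (unavailable) when no reads were recorded or when the source
    dialect carried only a total depth, so per-allele counts do not exist.
    """
    if not record.counts_exact:
        return None
    total = record.total_reads
    if total == 0:
        return None
    return record.counts[record.alt] / total


class Zygosity(str, enum.Enum):
    HOM_ALT = "hom_alt"
    HET = "het"
    AMBIGUOUS_LOW = "ambiguous_low"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class ZygosityCall:
    value: Zygosity
    fraction: float | None

    def __post_init__(self) -> None:
        if self.value is not Zygosity.UNAVAILABLE:
            assert self.fraction is not None and 0.0 <= self.fraction <= 1.0


def classify_zygosity(
    record: SnpRecord, het_band: tuple[float, float] = DEFAULT_HET_BAND
) -> ZygosityCall:
    """Classify a call from its mutant-read fraction.

    ``fraction >= hi`` -> homozygous-alternate; ``lo <= fraction < hi`` ->
    heterozygous; ``fraction < lo`` -> ambiguous (too few mutant reads);
    no usable counts -> unavailable.
    """
    lo, hi = het_band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid heterozygosity band ({lo}, {hi})")
    frac = mutant_read_fraction(record)
    if frac is None:
        return ZygosityCall(Zygosity.UNAVAILABLE, None)
    if frac >= hi:
        return ZygosityCall(Zygosity.HOM_ALT, frac)
    if frac >= lo:
        return ZygosityCall(Zygosity.HET, frac)
    return ZygosityCall(Zygosity.AMBIGUOUS_LOW, frac)


def render_percent(fraction: float | None) -> str:
    """Mutant-read percentage at 1 decimal place; empty when unavailable."""
    return "" if fraction is None else f"{fraction * 100:.1f}"


def build_data_table(
    datasets: list[SampleDataset],
    chrom: str,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> pd.DataFrame:
    """One row per call on ``chrom``, one section (sample block) per dataset.

    Columns carry every native field, the extras joined by ``|``, the
    mutant-read fraction at full precision, its rendering at one decimal
    place, and the zygosity call.  Within a section rows are sorted by
    position.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    c = normalize_chrom(chrom)
    rows = []
    for ds in datasets:
        for rec in ds.on_chrom(c):
            frac = mutant_read_fraction(rec)
            rows.append(
                {
                    "sample_id": ds.sample_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "score": rec.score,
                    "score_missing": rec.score_is_missing,
                    **{f"reads_{nt}": rec.counts[nt] for nt in NUCLEOTIDES},
                    "mutant_fraction": frac,
                    "mutant_pct": render_percent(frac),
                    "zygosity": classify_zygosity(rec, het_band).value.value,
                    "extras": "|".join(rec.extras),
                }
            )
    if not rows:
        warnings.warn(f"chromosome {c} absent from every dataset", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "sample_id", "chrom", "pos", "ref", "alt", "score", "score_missing",
                *(f"reads_{nt}" for nt in NUCLEOTIDES),
                "mutant_fraction", "mutant_pct", "zygosity", "extras",
            ]
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FrequencyEntry:
    """Occurrence of one SNP across the compared sample set."""

    key: SnpKey
    count: int
    frequency: float
    samples: tuple[str, ...]


@dataclass
class FrequencyReport:
    """Per-SNP frequency of appearance across samples, with a threshold cut.

    ``entries`` lists every SNP on the chromosome present in at least one
    sample, sorted by frequency (descending) then genomic order;
    ``surviving`` is the subset with ``frequency >= threshold`` (inclusive,
    so a threshold of 1.0 selects SNPs fixed in the sample set).
    """

    chrom: str
    n_samples: int
    threshold: float
    sample_ids: tuple[str, ...]
    entries: list[FrequencyEntry] = field(default_factory=list)

    @property
    def surviving(self) -> list[FrequencyEntry]:
        return [e for e in self.entries if e.frequency >= self.threshold]

    def bar_chart_data(self) -> list[tuple[str, float]]:
        """(label, frequency) pairs for the surviving SNPs."""
        return [(str(e.key), e.frequency) for e in self.surviving]

    def to_frame(self) -> pd.DataFrame:
        """Index table mirroring the bar graph: all entries + survival flag."""
        return pd.DataFrame(
            {
                "chrom": [e.key.chrom for e in self.entries],
                "pos": [e.key.pos for e in self.entries],
                "alt": [e.key.alt for e in self.entries],
                "count": [e.count for e in self.entries],
                "n_samples": self.n_samples,
                "frequency": [e.frequency for e in self.entries],
                "samples": [",".join(e.samples) for e in self.entries],
                "survives": [e.frequency >= self.threshold for e in self.entries],
            }
        )


def _membership(
    datasets: list[SampleDataset], chrom: str, match_position_only: bool
) -> dict[SnpKey, list[str]]:
    """Map each SNP key on ``chrom`` to the ordered sample ids carrying it."""
    carriers: dict[SnpKey, list[str]] = {}
    for ds in datasets:
        keys = {rec.key for rec in ds.on_chrom(chrom)}
        if match_position_only:
            # collapse alt: represent the position by alt="" sentinel
            keys = {SnpKey(k.chrom_rank, k.pos, "") for k in keys}
        for k in keys:
            carriers.setdefault(k, []).append(ds.sample_id)
    return carriers


def compare_samples(
    datasets: list[SampleDataset],
    chrom: str,
    threshold: float = 0.0,
    *,
    match_position_only: bool = False,
) -> FrequencyReport:
    """Frequency of appearance of each SNP across the selected samples.

    The denominator is the number of datasets passed in, i.e. the sample
    set the user selected for this comparison.  Comparing a single sample
    is permitted but warned, since every frequency is then 1.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if len({ds.sample_id for ds in datasets}) != len(datasets):
        raise ValueError("sample_ids must be unique within a comparison")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if len(datasets) < 2:
        warnings.warn("comparing a single sample: every frequency is 1", stacklevel=2)
    c = normalize_chrom(chrom)
    n = len(datasets)
    carriers = _membership(datasets, c, match_position_only)
    entries = [
        FrequencyEntry(key=k, count=len(ids), frequency=len(ids) / n, samples=tuple(sorted(ids)))
        for k, ids in carriers.items()
    ]
    entries.sort(key=lambda e: (-e.frequency, e.key))
    return FrequencyReport(
        chrom=c,
        n_samples=n,
        threshold=threshold,
        sample_ids=tuple(ds.sample_id for ds in datasets),
        entries=entries,
    )


@dataclass
class PresenceMatrix:
    """Boolean SNP x sample table for one chromosome."""

    chrom: str
    keys: list[SnpKey]
    sample_ids: list[str]
    cells: pd.DataFrame  # index: str(key) rows, columns: sample_ids, dtype bool

    def samples_with(self, key: SnpKey) -> list[str]:
        row = self.cells.loc[str(key)]
        return [s for s in self.sample_ids if bool(row[s])]

    def row_counts(self) -> dict[SnpKey, int]:
        sums = self.cells.sum(axis=1)
        return {k: int(sums[str(k)]) for k in self.keys}

    def to_frame(self) -> pd.DataFrame:
        """Export form: key columns, one 0/1 column per sample, sample listing."""
        df = pd.DataFrame(
            {
                "chrom": [k.chrom for k in self.keys],
                "pos": [k.pos for k in self.keys],
                "alt": [k.alt for k in self.keys],
            }
        )
        for s in self.sample_ids:
            df[s] = [int(self.cells.at[str(k), s]) for k in self.keys]
        df["samples"] = [",".join(self.samples_with(k)) for k in self.keys]
        return df


def snp_view(datasets: list[SampleDataset], chrom: str) -> PresenceMatrix:
    """Presence matrix over the union of SNPs on ``chrom``.

    Row sums over samples equal the occurrence counts of
    :func:`compare_samples` for every key; rows absent from every sample do
    not appear, so no all-false row exists.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    c = normalize_chrom(chrom)
    sample_ids = [ds.sample_id for ds in datasets]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample_ids must be unique within a view")
    per_sample = {ds.sample_id: {rec.key for rec in ds.on_chrom(c)} for ds in datasets}
    keys = sorted(set().union(*per_sample.values()) if per_sample else set())
    cells = pd.DataFrame(
        [[k in per_sample[s] for s in sample_ids] for k in keys],
        index=[str(k) for k in keys],
        columns=sample_ids,
        dtype=bool,
    )
    return PresenceMatrix(chrom=c, keys=keys, sample_ids=sample_ids, cells=cells)


def export_table(rows: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write a result table as delimited text with a header row.

    ``tsv`` uses tab separation; ``csv`` uses RFC-4180-style quoting, so the
    file loads cleanly in spreadsheet applications.
    """
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    rows.to_csv(Path(path), sep=sep, index=False, lineterminator="\n")
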