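"""Shared test utilities: independent oracles and randomized data builders.

The oracles here deliberately avoid the package's own code paths: the
frequency recount re-parses raw files with plain string splitting, and the
pgSnp validator checks emitted lines against the published field rules
rather than via PgSnpRecord.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from snptrack import Category, SampleDataset, SnpRecord

NUCLEOTIDES = ("A", "C", "G", "T")


def assert_datasets_equal(a: SampleDataset, b: SampleDataset) -> None:
    """Field-for-field record equality; source paths are allowed to differ."""
    assert a.sample_id == b.sample_id
    assert len(a.records) == len(b.records)
    for ra, rb in zip(a.records, b.records):
        assert ra == rb, f"{ra} != {rb}"


def fast_random_dataset(rng: np.random.Generator, sample_id: str = "S") -> SampleDataset:
    """Small random dataset exercising scores (incl. missing), extras, chroms."""
    n = int(rng.integers(1, 25))
    chrom_pool = ["1", "2", "10", "X", "Y", "MT"]
    used: set[tuple[str, int, str]] = set()
    records = []
    while len(records) < n:
        chrom = chrom_pool[int(rng.integers(0, len(chrom_pool)))]
        pos = int(rng.integers(1, 1_000_000))
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
        key = (chrom, pos, NUCLEOTIDES[alt_i])
        if key in used:
            continue
        used.add(key)
        counts = {nt: int(c) for nt, c in zip(NUCLEOTIDES, rng.integers(0, 60, size=4))}
        score_kind = int(rng.integers(0, 3))
        score = 0.0 if score_kind == 0 else (
            float(rng.integers(1, 100)) if score_kind == 1
            else round(float(rng.uniform(0.5, 99.5)), 2)
        )
        extras = []
        if rng.random() < 0.4:
            extras = [f"GENE{int(rng.integers(0, 50))}", ["novel", "known"][int(rng.integers(0, 2))]]
        records.append(
            SnpRecord(chrom=chrom, pos=pos, ref=NUCLEOTIDES[ref_i],
                      alt=NUCLEOTIDES[alt_i], score=score, counts=counts,
                      extras=extras)
        )
    return SampleDataset(sample_id=sample_id, records=records,
                         category=Category.UNSPECIFIED, source="synthetic")


def naive_frequency_recount(paths: dict[str, Path], chrom: str) -> dict[tuple[str, int, str], set[str]]:
    """Brute-force membership recount straight from raw native-format text.

    Independent of the package parser: splits on tabs, takes columns 1-4,
    normalizes the chromosome by stripping a leading 'chr' only.
    """
    carriers: dict[tuple[str, int, str], set[str]] = {}
    for sample_id, path in paths.items():
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            f = line.split("\t")
            c = f[0][3:] if f[0].lower().startswith("chr") else f[0]
            if c.upper() != chrom.upper():
                continue
            key = (c.upper(), int(f[1]), f[3].upper())
            carriers.setdefault(key, set()).add(sample_id)
    return carriers


def validate_pgsnp_line(line: str) -> list[str]:
    """Check one pgSnp data line against the published field definitions.

    Returns a list of violations (empty = conformant): 7 tab-separated
    fields; integer coordinates with chromEnd - chromStart == 1; allele
    count matching the '/'-token count of name and the ','-token counts of
    alleleFreq and alleleScores; numeric frequency/score tokens.
    """
    violations: list[str] = []
    fields = line.split("\t")
    if len(fields) != 7:
        return [f"expected 7 fields, got {len(fields)}"]
    chrom, start_s, end_s, name, count_s, freqs, scores = fields
    if not chrom.startswith("chr"):
        violations.append(f"chrom {chrom!r} lacks 'chr' prefix")
    try:
        start, end = int(start_s), int(end_s)
        if start < 0:
            violations.append("negative chromStart")
        if end - start != 1:
            violations.append(f"interval length {end - start} != 1")
    except ValueError:
        violations.append("non-integer coordinates")
    try:
        n = int(count_s)
    except ValueError:
        violations.append(f"non-integer alleleCount {count_s!r}")
        return violations
    alleles = name.split("/")
    if len(alleles) != n:
        violations.append(f"{len(alleles)} alleles in name vs alleleCount {n}")
    if any(a not in ("A", "C", "G", "T", "N") for a in alleles):
        violations.append(f"non-nucleotide allele in {name!r}")
    for label, toks in (("alleleFreq", freqs.split(",")), ("alleleScores", scores.split(","))):
        if len(toks) != n:
            violations.append(f"{label} has {len(toks)} tokens vs alleleCount {n}")
        for t in toks:
            try:
                float(t)
            except ValueError:
                violations.append(f"non-numeric {label} token {t!r}")
    return violations
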