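"""Native-format parsing, writing, dialect sniffing and VCF import."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import assert_datasets_equal
from snptrack import (
    CountsLayout,
    DuplicateKeyError,
    EmptyFileError,
    FormatDialect,
    MalformedLineError,
    SampleDataset,
    SnpRecord,
    UndecidableDialectError,
    import_vcf,
    parse_snp_file,
    parse_snp_lines,
    sniff_dialect,
    write_snp_file,
)

FOUR_NT = FormatDialect(CountsLayout.FOUR_NT)
REF_ALT = FormatDialect(CountsLayout.REF_ALT)
TOTAL = FormatDialect(CountsLayout.TOTAL)


# ---------------------------------------------------------------- parsing

def test_parse_four_nt_line():
    ds = parse_snp_lines(["1\t10583\tA\tG\t55\t12\t0\t13\t0"], FOUR_NT)
    (rec,) = ds.records
    assert rec.chrom == "1" and rec.pos == 10583
    assert rec.ref == "A" and rec.alt == "G"
    assert rec.score == 55 and not rec.score_is_missing
    assert rec.counts == {"A": 12, "C": 0, "G": 13, "T": 0}
    assert rec.extras == [] and rec.counts_exact


def test_score_zero_is_missing_but_carried():
    ds = parse_snp_lines(["2\t500\tC\tT\t0\t0\t8\t0\t8"], FOUR_NT)
    (rec,) = ds.records
    assert rec.score == 0.0
    assert rec.score_is_missing


def test_ref_alt_dialect_places_counts_under_ref_and_alt():
    ds = parse_snp_lines(["1\t100\tA\tG\t30\t12\t13"], REF_ALT)
    (rec,) = ds.records
    assert rec.counts == {"A": 12, "C": 0, "G": 13, "T": 0}
    assert rec.counts_exact


def test_total_dialect_flags_counts_unavailable():
    ds = parse_snp_lines(["1\t100\tA\tG\t30\t25"], TOTAL)
    (rec,) = ds.records
    assert rec.counts == {"A": 0, "C": 0, "G": 25, "T": 0}
    assert not rec.counts_exact


def test_extras_preserved_in_order():
    ds = parse_snp_lines(["1\t100\tA\tG\t30\t1\t2\t3\t4\tBRCA1\tnovel\tCDS"], FOUR_NT)
    assert ds.records[0].extras == ["BRCA1", "novel", "CDS"]


def test_chr_prefix_and_case_normalized():
    ds = parse_snp_lines(
        ["chrX\t5\ta\tg\t10\t1\t0\t1\t0", "chrM\t9\tC\tt\t10\t0\t1\t0\t1"], FOUR_NT
    )
    assert [r.chrom for r in ds.records] == ["X", "MT"]
    assert ds.records[0].ref == "A" and ds.records[0].alt == "G"


def test_records_sorted_by_chrom_then_pos():
    lines = [
        "MT\t5\tA\tG\t1\t1\t0\t1\t0",
        "2\t9\tA\tG\t1\t1\t0\t1\t0",
        "10\t3\tA\tG\t1\t1\t0\t1\t0",
        "2\t4\tA\tG\t1\t1\t0\t1\t0",
        "X\t1\tA\tG\t1\t1\t0\t1\t0",
    ]
    ds = parse_snp_lines(lines, FOUR_NT)
    assert [(r.chrom, r.pos) for r in ds.records] == [
        ("2", 4), ("2", 9), ("10", 3), ("X", 1), ("MT", 5)
    ]


@pytest.mark.parametrize(
    "line,reason",
    [
        ("1\t100\tA\tA\t10\t5\t0\t0\t0", "consensus and SNP"),  # ref == alt
        ("1\t100\tA\tG\t10\t5\t0", "fields"),  # too few columns
        ("1\t0\tA\tG\t10\t5\t0\t0\t0", "position"),  # pos < 1
        ("1\tx\tA\tG\t10\t5\t0\t0\t0", "position"),  # non-integer pos
        ("1\t100\tA\tG\t10\t5\t-1\t0\t0", "count"),  # negative count
        ("1\t100\tA\tG\t10\t5\tz\t0\t0", "count"),  # non-integer count
        ("1\t100\tZ\tG\t10\t5\t0\t0\t0", "nucleotide"),  # bad ref
        ("7q\t100\tA\tG\t10\t5\t0\t0\t0", "chromosome"),  # bad chrom
        ("1\t100\tA\tG\t-3\t5\t0\t0\t0", "score"),  # negative score
    ],
)
def test_malformed_lines_diagnosed_with_line_number(line, reason):
    with pytest.raises(MalformedLineError, match="line 1") as exc:
        parse_snp_lines([line], FOUR_NT)
    assert reason in str(exc.value)


def test_empty_file_rejected(tmp_path):
    p = tmp_path / "empty.txt"
    p.write_text("\n\n")
    with pytest.raises(EmptyFileError):
        parse_snp_file(p, FOUR_NT)


def test_duplicate_key_keeps_first_with_warning_or_errors_when_strict():
    lines = [
        "1\t100\tA\tG\t10\t5\t0\t5\t0",
        "1\t100\tA\tG\t99\t1\t0\t9\t0",
    ]
    with pytest.warns(UserWarning, match="duplicate"):
        ds = parse_snp_lines(lines, FOUR_NT)
    assert len(ds.records) == 1 and ds.records[0].score == 10
    with pytest.raises(DuplicateKeyError, match="line 2"):
        parse_snp_lines(lines, FOUR_NT, strict_duplicates=True)


def test_windows_line_endings_and_blank_lines_accepted(tmp_path):
    p = tmp_path / "crlf.txt"
    p.write_bytes(b"1\t100\tA\tG\t10\t5\t0\t5\t0\r\n\r\n2\t7\tC\tT\t9\t0\t4\t0\t4\r\n")
    ds = parse_snp_file(p, FOUR_NT)
    assert len(ds.records) == 2


# ---------------------------------------------------------------- sniffing

def test_sniffer_prefers_four_nt_then_ref_alt_then_total(tmp_path):
    cases = {
        "a.txt": ("1\t100\tA\tG\t10\t5\t0\t5\t0\n", CountsLayout.FOUR_NT),
        "b.txt": ("1\t100\tA\tG\t10\t5\t7\tBRCA1\n", CountsLayout.REF_ALT),
        "c.txt": ("1\t100\tA\tG\t10\t25\n", CountsLayout.TOTAL),
        "d.txt": ("1\t100\tA\tG\t10\t25\tgene\n", CountsLayout.TOTAL),
    }
    for name, (content, expected) in cases.items():
        p = tmp_path / name
        p.write_text(content)
        assert sniff_dialect(p).counts_layout is expected, name


def test_sniffer_undecidable_on_non_numeric_count_column(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("1\t100\tA\tG\t10\tgene\tnovel\n")
    with pytest.raises(UndecidableDialectError):
        sniff_dialect(p)


# ---------------------------------------------------------------- round trip

@st.composite
def snp_records(draw):
    chrom = draw(st.sampled_from(["1", "2", "10", "22", "X", "Y", "MT"]))
    pos = draw(st.integers(min_value=1, max_value=10**7))
    ref, alt = draw(
        st.tuples(st.sampled_from("ACGTN"), st.sampled_from("ACGTN")).filter(
            lambda p: p[0] != p[1]
        )
    )
    score = draw(
        st.one_of(
            st.just(0.0),
            st.integers(1, 255).map(float),
            st.floats(0.01, 999.0, allow_nan=False).map(lambda x: round(x, 3)),
        )
    )
    counts = {
        nt: draw(st.integers(0, 500)) for nt in "ACGT"
    }
    extras = draw(
        st.lists(st.text(alphabet="ACGTacgt0123456789._-novelkwn", min_size=1, max_size=8),
                 max_size=3)
    )
    return SnpRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, score=score,
                     counts=counts, extras=extras)


@st.composite
def sample_datasets(draw):
    recs = draw(st.lists(snp_records(), min_size=1, max_size=12))
    unique = {r.key: r for r in recs}
    return SampleDataset(sample_id="H", records=list(unique.values()))


@given(sample_datasets())
def test_round_trip_identity_four_nt(tmp_path_factory, ds):
    """parse(write(d)) reproduces every field of every record."""
    p = tmp_path_factory.mktemp("rt") / "d.txt"
    write_snp_file(ds, p, FOUR_NT)
    back = parse_snp_file(p, FOUR_NT, sample_id="H")
    assert_datasets_equal(ds, back)


def test_written_file_is_headerless_tab_separated_with_trailing_newline(tmp_path):
    ds = parse_snp_lines(["1\t100\tA\tG\t10\t5\t0\t5\t0\tBRCA1\tnovel"], FOUR_NT)
    p = tmp_path / "out.txt"
    write_snp_file(ds, p)
    text = p.read_text()
    assert text == "1\t100\tA\tG\t10\t5\t0\t5\t0\tBRCA1\tnovel\n"


# ---------------------------------------------------------------- VCF import

VCF_TEXT = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##contig=<ID=1>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE1
    1\t10583\t.\tA\tG\t55\tPASS\t.\tGT:AD\t0/1:12,13
    1\t20000\t.\tA\tG,T\t60\tPASS\t.\tGT:AD\t1/2:10,5,5
    1\t30000\t.\tAT\tA\t50\tPASS\t.\tGT:AD\t0/1:9,9
    """
)


def test_import_vcf_maps_fields_splits_multiallelics_and_skips_indels(tmp_path):
    p = tmp_path / "calls.vcf"
    p.write_text(VCF_TEXT)
    ds, skipped = import_vcf(p, sample_id="V1")
    assert skipped == 1  # the indel
    assert len(ds.records) == 3
    first = ds.records[0]
    assert (first.chrom, first.pos, first.ref, first.alt) == ("1", 10583, "A", "G")
    assert first.score == 55
    assert first.counts == {"A": 12, "C": 0, "G": 13, "T": 0}
    multi = {(r.pos, r.alt): r for r in ds.records[1:]}
    assert multi[(20000, "G")].counts == {"A": 10, "C": 0, "G": 5, "T": 0}
    assert multi[(20000, "T")].counts == {"A": 10, "C": 0, "G": 0, "T": 5}
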