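"""SD table reading, filtering, region merging and network construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdnet import (
    SDAlignment,
    build_network,
    filter_alignments,
    merge_to_regions,
    read_cnvs,
    read_network,
    read_sd_alignments,
    write_network,
)
from sdnet.network import is_autosome

from conftest import brute_force_regions


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

UCSC_FIELDS = {
    "chrom": "chr1", "chromStart": "100", "chromEnd": "2100",
    "name": "chr1:5000", "score": "0", "strand": "+",
    "otherChrom": "chr1", "otherStart": "5000", "otherEnd": "7000",
    "otherSize": "2000", "uid": "1", "posBasesHit": "1000",
    "testResult": "N/A", "verdict": "N/A", "chits": "N/A", "ccov": "N/A",
    "alignfile": "align.psl", "alignL": "2000", "indelN": "0",
    "indelS": "0", "alignB": "2000", "matchB": "1900", "mismatchB": "100",
    "transitionsB": "50", "transversionsB": "50", "fracMatch": "0.95",
    "fracMatchIndel": "0.95", "jcK": "0.05", "k2K": "0.05",
}


def _write_ucsc(path, rows):
    from sdnet.network import _UCSC_COLUMNS
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_UCSC_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in _UCSC_COLUMNS) + "\n")


def test_ucsc_row_passthrough(tmp_path):
    path = tmp_path / "sd.tsv"
    _write_ucsc(path, [UCSC_FIELDS])
    (aln,) = read_sd_alignments(path, dialect="ucsc")
    assert aln.chrom_a == "chr1" and (aln.start_a, aln.end_a) == (100, 2100)
    assert aln.chrom_b == "chr1" and (aln.start_b, aln.end_b) == (5000, 7000)
    assert aln.identity == pytest.approx(0.95)
    assert aln.aln_length == 2000


def test_malformed_row_skipped_with_warning(tmp_path):
    path = tmp_path / "sd.tsv"
    good = "\t".join(["chr1", "0", "1500", "chr2", "0", "1500", "0.95"])
    with open(path, "w") as fh:
        fh.write(good + "\nchr1\tnot_a_number\n")
    with pytest.warns(UserWarning, match="line 2"):
        records = read_sd_alignments(path, dialect="bedpe")
    assert len(records) == 1
    with pytest.raises(ValueError, match="line 2"):
        read_sd_alignments(path, dialect="bedpe", strict=True)


def test_percent_identity_normalised(tmp_path):
    path = tmp_path / "sd.tsv"
    path.write_text("chr1\t0\t1500\tchr2\t0\t1500\t95.5\n")
    (aln,) = read_sd_alignments(path, dialect="bedpe")
    assert aln.identity == pytest.approx(0.955)


def test_sedef_dialect_short_and_long_rows(tmp_path):
    short = tmp_path / "short.tsv"
    short.write_text("chr1\t0\t2000\tchr3\t100\t2100\t0.97\n")
    (aln,) = read_sd_alignments(short, dialect="sedef")
    assert aln.identity == pytest.approx(0.97)
    long_fields = ["chr1", "0", "2000", "chr3", "100", "2100", "S1", "0",
                   "+", "+", "2100", "2050", "c", "0", "0", "2000", "1900",
                   "100", "50", "50", "0.93"]
    long = tmp_path / "long.tsv"
    long.write_text("\t".join(long_fields) + "\n")
    (aln,) = read_sd_alignments(long, dialect="sedef")
    assert aln.identity == pytest.approx(0.93)
    assert aln.aln_length == 2050


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _aln(chrom_a="chr1", chrom_b="chr2", length=1500, identity=0.95):
    return SDAlignment(chrom_a, 0, length, chrom_b, 0, length, identity,
                       length)


@pytest.mark.parametrize("aln,kwargs,kept", [
    (_aln(length=999, identity=0.99), {}, False),           # too short
    (_aln(length=1500, identity=0.85), {}, False),          # identity low
    (_aln(length=1500, identity=0.85),
     dict(min_len=500, min_identity=0.70), True),           # reduced cut-offs
    (_aln(chrom_a="chrX"), {}, False),                      # sex chromosome
    (_aln(chrom_a="chrX"), dict(autosomes_only=False), True),
    (_aln(), {}, True),
])
def test_filter_cutoffs(aln, kwargs, kept):
    assert (len(filter_alignments([aln], **kwargs)) == 1) is kept


def test_filter_mask_excludes_overlapping_sides():
    aln = _aln()
    assert filter_alignments([aln], exclude_mask=[("chr1", 1000, 1100)]) == []
    assert len(filter_alignments([aln],
                                 exclude_mask=[("chr1", 5000, 6000)])) == 1


def test_is_autosome():
    assert is_autosome("chr7") and is_autosome("12")
    assert not any(map(is_autosome, ["chrX", "chrY", "chrM", "chrUn",
                                     "chr1_alt"]))


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_toy_three_regions(toy_alignments):
    regions, side_map = merge_to_regions(toy_alignments)
    coords = {(r.chrom, r.start, r.end) for r in regions}
    assert coords == {("chr1", 100, 2600), ("chr1", 5000, 7000),
                      ("chr2", 100, 1200)}
    assert len(side_map) == 4
    # partition: every side mapped to exactly one region
    assert sum(len(r.member_sides) for r in regions) == 4


def test_single_alignment_two_regions():
    aln = _aln()
    regions, _ = merge_to_regions([aln])
    assert len(regions) == 2
    assert {(r.start, r.end) for r in regions} == {(0, 1500)}


def test_touching_intervals_merge_only_with_padding():
    alns = [SDAlignment("chr1", 0, 1000, "chr3", 0, 1000, 0.95, 1000),
            SDAlignment("chr1", 1000, 2000, "chr4", 0, 1000, 0.95, 1000)]
    regions0, _ = merge_to_regions(alns, padding=0)
    assert len(regions0) == 4  # half-open: touching does not overlap
    regions1, _ = merge_to_regions(alns, padding=1)
    assert len(regions1) == 3
    # bounds stay unpadded
    merged = next(r for r in regions1 if len(r.member_sides) == 2)
    assert (merged.start, merged.end) == (0, 2000)


def test_negative_padding_error():
    aln = _aln(length=1500)
    with pytest.raises(ValueError, match="padding"):
        merge_to_regions([aln], padding=-800)


def test_merge_idempotent_on_disjoint():
    alns = [SDAlignment("chr1", i * 10_000, i * 10_000 + 2000,
                        "chr2", i * 10_000, i * 10_000 + 2000, 0.95, 2000)
            for i in range(5)]
    regions, _ = merge_to_regions(alns)
    assert len(regions) == 10
    assert all(len(r.member_sides) == 1 for r in regions)


@given(st.lists(
    st.tuples(st.sampled_from(["chr1", "chr2"]),
              st.integers(0, 5000), st.integers(1000, 4000),
              st.sampled_from(["chr1", "chr2", "chr3"]),
              st.integers(0, 5000), st.integers(1000, 4000)),
    min_size=1, max_size=50))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_merge_matches_brute_force_closure(raw):
    alns = [SDAlignment(ca, sa, sa + la, cb, sb, sb + lb, 0.95, la)
            for ca, sa, la, cb, sb, lb in raw]
    regions, side_map = merge_to_regions(alns)
    intervals = []
    for aln in alns:
        intervals.extend(aln.sides)
    expected = brute_force_regions(intervals)
    assert {(r.chrom, r.start, r.end) for r in regions} == expected
    # partition invariant
    assert sum(len(r.member_sides) for r in regions) == 2 * len(alns)


@given(st.lists(
    st.tuples(st.integers(0, 30_000), st.integers(1000, 5000),
              st.integers(0, 30_000), st.integers(1000, 5000)),
    min_size=1, max_size=25),
    st.sampled_from([0, 10, 100, 1000]))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_padding_monotonicity(raw, padding):
    alns = [SDAlignment("chr1", sa, sa + la, "chr1", sb, sb + lb, 0.95, la)
            for sa, la, sb, lb in raw]
    n_plain = len(merge_to_regions(alns, padding=0)[0])
    n_padded = len(merge_to_regions(alns, padding=padding)[0])
    assert n_padded <= n_plain
    net_plain = build_network(*merge_to_regions(alns, padding=0), alns)
    net_padded = build_network(*merge_to_regions(alns, padding=padding), alns)
    assert sum(net_padded.self_loops.values()) >= \
        sum(net_plain.self_loops.values())


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def test_build_network_toy(toy_network):
    net = toy_network
    assert net.n_nodes == 3
    assert net.n_edges == 2
    assert sum(net.self_loops.values()) == 0


def test_self_loop_when_sides_merge():
    aln = SDAlignment("chr1", 0, 2000, "chr1", 1500, 3500, 0.95, 2000)
    net = build_network(*merge_to_regions([aln]), [aln])
    assert net.n_nodes == 1
    assert net.n_edges == 0
    assert net.self_loops == {0: 1}


def test_multiplicity_counted_and_trimmed():
    alns = [SDAlignment("chr1", 0, 2000, "chr2", 0, 2000, 0.95, 2000),
            SDAlignment("chr1", 100, 1900, "chr2", 100, 1900, 0.96, 1800)]
    net = build_network(*merge_to_regions(alns), alns)
    assert net.n_nodes == 2
    assert net.n_edges == 1  # trimmed
    assert list(net.multiplicity.values()) == [2]
    assert net.double_edge_count(0) == 1


def test_degrees_are_neighbor_counts(toy_network):
    g = toy_network.graph
    for node in g.nodes():
        assert g.degree[node] == len(set(g.neighbors(node)))


def test_network_roundtrip(tmp_path, toy_network):
    write_network(toy_network, tmp_path)
    loaded = read_network(tmp_path)
    assert loaded.n_nodes == toy_network.n_nodes
    assert set(loaded.multiplicity) == set(toy_network.multiplicity)
    assert loaded.self_loops == toy_network.self_loops
    coords = {(r.chrom, r.start, r.end) for r in loaded.regions}
    assert coords == {(r.chrom, r.start, r.end)
                      for r in toy_network.regions}


# ---------------------------------------------------------------------------
# CNV input
# ---------------------------------------------------------------------------

def test_read_cnvs_bed_mac(tmp_path):
    path = tmp_path / "cnv.bed"
    path.write_text("chr1\t100\t500\t7\nchrX\t0\t100\t5\n")
    records = read_cnvs(path, dialect="bed_mac")
    assert len(records) == 1  # chrX excluded
    assert records[0].mac == 7


def test_read_cnvs_vcf_mac_rule(tmp_path):
    # 5 diploid samples, 3 carrying one DUP allele each: c=3, 2n-c=7, MAC=3
    vcf = tmp_path / "sv.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n'
        '##ALT=<ID=DUP,Description="Duplication">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        "S1\tS2\tS3\tS4\tS5\n"
        "chr2\t1001\tsv1\tA\t<DUP>\t.\tPASS\tEND=5000\tGT\t"
        "0|1\t0|0\t1|0\t0|1\t0|0\n"
        "chrX\t2001\tsv2\tA\t<DUP>\t.\tPASS\tEND=3000\tGT\t"
        "0|1\t0|0\t0|0\t0|0\t0|0\n")
    records = read_cnvs(vcf, dialect="vcf")
    assert len(records) == 1
    rec = records[0]
    assert rec.mac == 3
    assert (rec.chrom, rec.start, rec.end) == ("chr2", 1000, 5000)
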