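"""Segmental-duplication tables, region merging and SD-network construction.

A segmental duplication (SD) is reported as a pairwise local alignment
between two genomic intervals.  Overlapping alignment *sides* are merged
into maximal *duplicated regions*; regions become the nodes of the SD
network and an (undirected) edge is placed between two regions whenever
at least one alignment joins them.  The network is kept in two views: the
trimmed simple graph (no self-loops, no parallel edges) used for all
topological analyses, and the untrimmed multiplicity/self-loop counts
needed by the region-length feature model.

Coordinates are 0-based half-open throughout (BED convention).  Intervals
that merely touch (end == start) do not overlap and are not merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SDAlignment",
    "DuplicatedRegion",
    "SDNetwork",
    "CNVRecord",
    "read_sd_alignments",
    "filter_alignments",
    "merge_to_regions",
    "build_network",
    "build_network_from_table",
    "read_cnvs",
    "read_bed",
    "write_regions_bed",
    "write_network",
    "read_network",
    "is_autosome",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDAlignment:
    """One pairwise local alignment between two genomic intervals.

    ``identity`` is a fraction in [0, 1]; ``aln_length`` is the alignment
    length in bp (the span of side A unless the table reports its own
    alignment length column).
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float
    aln_length: int

    def __post_init__(self) -> None:
        if not (self.start_a < self.end_a and self.start_b < self.end_b):
            raise ValueError(f"degenerate interval in alignment: {self}")
        if self.aln_length < 1:
            raise ValueError(f"alignment length < 1: {self}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity outside [0, 1]: {self}")

    @property
    def sides(self):
        return (
            (self.chrom_a, self.start_a, self.end_a),
            (self.chrom_b, self.start_b, self.end_b),
        )


@dataclass(frozen=True)
class DuplicatedRegion:
    """Maximal union of overlapping alignment sides; a node of the network."""

    region_id: int
    chrom: str
    start: int
    end: int
    member_sides: frozenset = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNVRecord:
    """A copy-number variant with its minor allele count in the cohort."""

    chrom: str
    start: int
    end: int
    mac: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate CNV interval: {self}")
        if self.mac < 1:
            raise ValueError(f"minor allele count < 1: {self}")


class SDNetwork:
    """SD network with a trimmed simple-graph view plus untrimmed counts.

    Attributes
    ----------
    graph : networkx.Graph
        Trimmed view: one edge per connected region pair, no self-loops.
        Nodes are region ids and carry ``chrom``, ``start``, ``end`` and
        ``length`` attributes.
    multiplicity : dict[tuple[int, int], int]
        Number of alignments supporting each (sorted) region pair.
    self_loops : dict[int, int]
        Number of alignments whose two sides fall into the same region.
    regions : list[DuplicatedRegion]
    """

    def __init__(self, regions, multiplicity, self_loops):
        self.regions = list(regions)
        self.multiplicity = dict(multiplicity)
        self.self_loops = dict(self_loops)
        g = nx.Graph()
        for r in self.regions:
            g.add_node(r.region_id, chrom=r.chrom, start=r.start, end=r.end,
                       length=r.length)
        for (a, b), _count in self.multiplicity.items():
            g.add_edge(a, b)
        self.graph = g

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: int) -> int:
        return self.graph.degree[node]

    def double_edge_count(self, node: int) -> int:
        """Parallel-alignment surplus of ``node`` in the untrimmed view."""
        total = 0
        for nbr in self.graph.neighbors(node):
            pair = (node, nbr) if node < nbr else (nbr, node)
            total += self.multiplicity[pair] - 1
        return total

    def self_loop_count(self, node: int) -> int:
        return self.self_loops.get(node, 0)

    def __repr__(self) -> str:
        return (f"SDNetwork(nodes={self.n_nodes}, edges={self.n_edges}, "
                f"self_loop_alignments={sum(self.self_loops.values())})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

#: column layout of the UCSC genomicSuperDups track (without the leading bin)
_UCSC_COLUMNS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "otherChrom", "otherStart", "otherEnd", "otherSize", "uid",
    "posBasesHit", "testResult", "verdict", "chits", "ccov", "alignfile",
    "alignL", "indelN", "indelS", "alignB", "matchB", "mismatchB",
    "transitionsB", "transversionsB", "fracMatch", "fracMatchIndel",
    "jcK", "k2K",
]


def is_autosome(chrom: str) -> bool:
    """True for plain numbered chromosomes (``chr7``/``7``), excluding sex
    chromosomes, organelles and unplaced/alt contigs."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.isdigit()


def _normalise_identity(value: float) -> float:
    return value / 100.0 if value > 1.0 else value


def _parse_row_ucsc(fields):
    # tolerate the optional leading `bin` column of table-browser dumps
    if len(fields) >= len(_UCSC_COLUMNS) + 1 and fields[0].isdigit() \
            and not fields[0].startswith("chr"):
        fields = fields[1:]
    row = dict(zip(_UCSC_COLUMNS, fields))
    start_a, end_a = int(row["chromStart"]), int(row["chromEnd"])
    return SDAlignment(
        chrom_a=row["chrom"], start_a=start_a, end_a=end_a,
        chrom_b=row["otherChrom"], start_b=int(row["otherStart"]),
        end_b=int(row["otherEnd"]),
        identity=_normalise_identity(float(row["fracMatch"])),
        aln_length=int(row["alignB"]) if row.get("alignB") else end_a - start_a,
    )


def _parse_row_sedef(fields):
    # SEDEF final output: BEDPE intervals first, fracMatch at column 21 when
    # the full record is present; short BEDPE-like tables carry identity in
    # column 7.
    start_a, end_a = int(fields[1]), int(fields[2])
    if len(fields) >= 21:
        identity = float(fields[20])
        aln_length = int(float(fields[11]))
    else:
        identity = float(fields[6])
        aln_length = end_a - start_a
    return SDAlignment(
        chrom_a=fields[0], start_a=start_a, end_a=end_a,
        chrom_b=fields[3], start_b=int(fields[4]), end_b=int(fields[5]),
        identity=_normalise_identity(identity),
        aln_length=aln_length,
    )


def _parse_row_bedpe(fields):
    start_a, end_a = int(fields[1]), int(fields[2])
    return SDAlignment(
        chrom_a=fields[0], start_a=start_a, end_a=end_a,
        chrom_b=fields[3], start_b=int(fields[4]), end_b=int(fields[5]),
        identity=_normalise_identity(float(fields[6])),
        aln_length=end_a - start_a,
    )


_PARSERS = {"ucsc": _parse_row_ucsc, "sedef": _parse_row_sedef,
            "bedpe": _parse_row_bedpe}


def read_sd_alignments(path, dialect="ucsc", strict=False, genome=None):
    """Read a pairwise SD alignment table.

    Parameters
    ----------
    path : str or Path
        Tab-separated table; ``#``-prefixed header lines are skipped.
    dialect : {"ucsc", "sedef", "bedpe"}
        ``ucsc`` — genomicSuperDups layout (0-based half-open);
        ``sedef`` — SEDEF final output (BEDPE intervals + fracMatch);
        ``bedpe`` — 7 columns: two intervals plus identity.
    strict : bool
        If True malformed rows raise; otherwise they are skipped with a
        warning naming the line.
    genome : dict[str, int], optional
        Chromosome sizes; rows naming other chromosomes are skipped with a
        warning (raise in strict mode).
    """
    try:
        parse = _PARSERS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect: {dialect!r}") from None
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                aln = parse(fields)
            except (ValueError, IndexError, KeyError) as exc:
                if strict:
                    raise ValueError(
                        f"{path}: malformed row at line {lineno}: {exc}"
                    ) from exc
                warnings.warn(f"{path}: skipping malformed row at line "
                              f"{lineno}: {exc}")
                continue
            if genome is not None and (aln.chrom_a not in genome
                                       or aln.chrom_b not in genome):
                msg = (f"{path}: unknown chromosome at line {lineno}: "
                       f"{aln.chrom_a}/{aln.chrom_b}")
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg)
                continue
            records.append(aln)
    return records


def filter_alignments(alns, min_len=1000, min_identity=0.90,
                      autosomes_only=True, exclude_mask=None):
    """Apply the SD definition cut-offs.

    Keeps alignments with ``aln_length >= min_len`` and
    ``identity >= min_identity``; with ``autosomes_only`` both sides must lie
    on numbered chromosomes; with an ``exclude_mask`` (iterable of
    ``(chrom, start, end)``) neither side may overlap a masked interval.
    """
    if min_len < 0 or min_identity < 0:
        raise ValueError("thresholds must be nonnegative")
    mask_by_chrom = {}
    if exclude_mask is not None:
        for chrom, start, end in exclude_mask:
            mask_by_chrom.setdefault(chrom, []).append((start, end))

    def masked(chrom, start, end):
        for mstart, mend in mask_by_chrom.get(chrom, ()):
            if start < mend and mstart < end:
                return True
        return False

    kept = []
    for aln in alns:
        if aln.aln_length < min_len or aln.identity < min_identity:
            continue
        if autosomes_only and not (is_autosome(aln.chrom_a)
                                   and is_autosome(aln.chrom_b)):
            continue
        if mask_by_chrom and any(masked(*side) for side in aln.sides):
            continue
        kept.append(aln)
    return kept


# ---------------------------------------------------------------------------
# region merging
# ---------------------------------------------------------------------------

def merge_to_regions(alns, padding=0, chrom_sizes=None):
    """Merge alignment sides into maximal duplicated regions.

    Every alignment contributes its two sides.  Each side is extended by
    ``padding`` bp on both ends (clipped at 0 and at the chromosome end when
    ``chrom_sizes`` is given) *for the purpose of clustering only*: sides
    whose padded intervals share at least one bp are merged transitively.
    Region bounds are recorded unpadded (the union of the original sides in
    the cluster), so padding perturbs the topology but not region lengths.

    Returns
    -------
    regions : list[DuplicatedRegion]
    side_to_region : dict[(int, str), int]
        Maps ``(alignment index, 'a'|'b')`` to a region id.
    """
    sides = []  # (chrom, padded_start, padded_end, start, end, key)
    for idx, aln in enumerate(alns):
        for side_label, (chrom, start, end) in zip("ab", aln.sides):
            pstart, pend = start - padding, end + padding
            if padding < 0 and pstart >= pend:
                raise ValueError(
                    f"negative padding {padding} collapses side "
                    f"({chrom}:{start}-{end}) of alignment {idx}")
            pstart = max(pstart, 0)
            if chrom_sizes is not None and chrom in chrom_sizes:
                pend = min(pend, chrom_sizes[chrom])
            sides.append((chrom, pstart, pend, start, end, (idx, side_label)))

    regions = []
    side_to_region = {}
    by_chrom = {}
    for side in sides:
        by_chrom.setdefault(side[0], []).append(side)

    for chrom in sorted(by_chrom):
        chrom_sides = sorted(by_chrom[chrom], key=lambda s: (s[1], s[2]))
        cluster = []
        cluster_pend = -1
        for side in chrom_sides:
            if cluster and side[1] >= cluster_pend:  # no 1-bp overlap
                regions.append(_close_cluster(len(regions), chrom, cluster,
                                              side_to_region))
                cluster = []
                cluster_pend = -1
            cluster.append(side)
            cluster_pend = max(cluster_pend, side[2])
        if cluster:
            regions.append(_close_cluster(len(regions), chrom, cluster,
                                          side_to_region))
    return regions, side_to_region


def _close_cluster(region_id, chrom, cluster, side_to_region):
    start = min(s[3] for s in cluster)
    end = max(s[4] for s in cluster)
    members = frozenset(s[5] for s in cluster)
    for s in cluster:
        side_to_region[s[5]] = region_id
    return DuplicatedRegion(region_id=region_id, chrom=chrom, start=start,
                            end=end, member_sides=members)


def build_network(regions, side_to_region, alns) -> SDNetwork:
    """Construct the SD network from merged regions and their alignments."""
    multiplicity = {}
    self_loops = {}
    for idx in range(len(alns)):
        try:
            ra = side_to_region[(idx, "a")]
            rb = side_to_region[(idx, "b")]
        except KeyError as exc:
            raise ValueError(f"alignment {idx} has an unmapped side") from exc
        if ra == rb:
            self_loops[ra] = self_loops.get(ra, 0) + 1
        else:
            pair = (ra, rb) if ra < rb else (rb, ra)
            multiplicity[pair] = multiplicity.get(pair, 0) + 1
    return SDNetwork(regions, multiplicity, self_loops)


def build_network_from_table(path, dialect="ucsc", min_len=1000,
                             min_identity=0.90, autosomes_only=True,
                             exclude_mask=None, padding=0,
                             chrom_sizes=None) -> SDNetwork:
    """One-call pipeline: read, filter, merge, build."""
    alns = read_sd_alignments(path, dialect=dialect)
    alns = filter_alignments(alns, min_len=min_len, min_identity=min_identity,
                             autosomes_only=autosomes_only,
                             exclude_mask=exclude_mask)
    regions, side_to_region = merge_to_regions(alns, padding=padding,
                                               chrom_sizes=chrom_sizes)
    return build_network(regions, side_to_region, alns)


# ---------------------------------------------------------------------------
# CNV input
# ---------------------------------------------------------------------------

def read_cnvs(path, dialect="bed_mac", autosomes_only=True):
    """Read CNV calls with minor allele counts.

    ``bed_mac`` — 4 columns: chrom, start, end, MAC.
    ``vcf`` — a (possibly structural-variant) VCF with per-sample genotypes;
    the MAC of a record is ``min(c, 2n - c)`` where ``c`` is the number of
    non-reference allele occurrences over the ``n`` called diploid samples.
    Records with MAC 0 (monomorphic) are skipped.
    """
    records = []
    if dialect == "bed_mac":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}: line {lineno}: expected 4 "
                                     "columns (chrom, start, end, mac)")
                chrom = fields[0]
                if autosomes_only and not is_autosome(chrom):
                    continue
                records.append(CNVRecord(chrom, int(fields[1]),
                                         int(fields[2]), int(fields[3])))
    elif dialect == "vcf":
        from cyvcf2 import VCF
        vcf = VCF(str(path), gts012=False)
        for variant in vcf:
            chrom = variant.CHROM
            if autosomes_only and not is_autosome(chrom):
                continue
            gts = variant.genotypes
            if gts is None:
                raise ValueError(f"{path}: record {chrom}:{variant.POS} "
                                 "has no genotypes")
            count = 0
            n_called = 0
            for gt in gts:
                alleles = [a for a in gt[:-1] if a >= 0]
                if not alleles:
                    continue
                n_called += 1
                count += sum(1 for a in alleles if a > 0)
            if n_called == 0:
                raise ValueError(f"{path}: record {chrom}:{variant.POS} "
                                 "has no called genotypes")
            mac = min(count, 2 * n_called - count)
            if mac < 1:
                continue
            end = variant.INFO.get("END", variant.POS + max(
                len(variant.REF) - 1, 1))
            records.append(CNVRecord(chrom, variant.POS - 1, int(end), mac))
    else:
        raise ValueError(f"unknown CNV dialect: {dialect!r}")
    return records


def read_bed(path):
    """Read a BED3(+) file into a list of (chrom, start, end) tuples."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


# ---------------------------------------------------------------------------
# round-trip output
# ---------------------------------------------------------------------------

def write_regions_bed(net: SDNetwork, path) -> None:
    with open(path, "w") as fh:
        for r in net.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def write_network(net: SDNetwork, out_dir) -> None:
    """Write node-attribute and edge-list TSVs (plus self-loop counts)."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [(r.region_id, r.chrom, r.start, r.end, r.length,
          net.self_loops.get(r.region_id, 0)) for r in net.regions],
        columns=["region_id", "chrom", "start", "end", "length",
                 "self_loops"])
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [(a, b, m) for (a, b), m in sorted(net.multiplicity.items())],
        columns=["region_id_a", "region_id_b", "multiplicity"])
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)


def read_network(in_dir) -> SDNetwork:
    from pathlib import Path
    inp = Path(in_dir)
    nodes = pd.read_csv(inp / "nodes.tsv", sep="\t")
    edges = pd.read_csv(inp / "edges.tsv", sep="\t")
    regions = [DuplicatedRegion(int(r.region_id), str(r.chrom), int(r.start),
                                int(r.end)) for r in nodes.itertuples()]
    self_loops = {int(r.region_id): int(r.self_loops)
                  for r in nodes.itertuples() if r.self_loops}
    multiplicity = {(int(r.region_id_a), int(r.region_id_b)):
                    int(r.multiplicity) for r in edges.itertuples()}
    return SDNetwork(regions, multiplicity, self_loops)
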