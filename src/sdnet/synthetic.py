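"""Ground-truth generator: duplication histories with secondary alignments.

A linear multi-chromosome genome accumulates copy–paste duplication
events.  Each event copies a source interval (drawn uniformly from the
existing sequence, or preferentially from already-duplicated sequence)
into a previously empty locus.  When a source overlaps material that was
itself copied earlier, the new copy shares ancestry with every other copy
of that material, which produces *secondary* alignments — alignments that
do not correspond to a duplication event themselves.

The generator works on a static coordinate frame: insertions consume
pre-reserved empty space at the end of each chromosome instead of
shifting coordinates, so every emitted coordinate stays valid for the
whole history and all oracles are exact.  Ancestry is tracked per
contiguous run down to the original (pre-duplication) coordinate space;
two genomic intervals align exactly when their ancestral images overlap.

No nucleotide sequence is simulated; identity values decay linearly with
event age and exist only to exercise the SD filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import CNVRecord, SDAlignment

__all__ = [
    "DuplicationEvent",
    "SimulatedHistory",
    "simulate_duplication_history",
    "ground_truth_network",
    "simulate_cnv_table",
]


@dataclass(frozen=True)
class DuplicationEvent:
    """One copy–paste event on the static coordinate frame."""

    index: int
    source_chrom: str
    source_start: int
    source_end: int
    insert_chrom: str
    insert_start: int
    preferential: bool

    @property
    def length(self) -> int:
        return self.source_end - self.source_start


@dataclass
class SimulatedHistory:
    """Full record of a simulated duplication history.

    ``copy_segments`` are ``(gstart, gend, astart, event)`` runs mapping
    inserted sequence to its ancestral (original-frame) coordinates in
    global linear coordinates (chromosome i occupies
    ``[i*chrom_len, (i+1)*chrom_len)``); ``identity_segments`` are
    ``(gstart, gend, event)`` runs of original sequence that served as a
    duplication source (they map to themselves).
    """

    n_chroms: int
    chrom_len: int
    original_len: int
    events: list = field(default_factory=list)
    copy_segments: list = field(default_factory=list)
    identity_segments: list = field(default_factory=list)

    # -- coordinates -------------------------------------------------------
    def chrom_name(self, index: int) -> str:
        return f"chr{index + 1}"

    def to_chrom(self, gpos: int):
        ci, pos = divmod(gpos, self.chrom_len)
        return self.chrom_name(ci), pos

    def to_global(self, chrom: str, pos: int) -> int:
        ci = int(chrom[3:]) - 1
        return ci * self.chrom_len + pos

    @property
    def chrom_sizes(self) -> dict:
        return {self.chrom_name(i): self.chrom_len
                for i in range(self.n_chroms)}

    # -- homology segments -------------------------------------------------
    def _all_segments(self):
        """(gstart, gend, astart, event) for copies and identity sources."""
        segs = list(self.copy_segments)
        segs.extend((s, e, s, ev) for s, e, ev in self.identity_segments)
        return segs

    def _raw_alignment_pairs(self):
        """Ancestral intersections of all segment pairs, un-merged."""
        segs = self._all_segments()
        pairs = []
        for i in range(len(segs)):
            gi, gi_end, ai, evi = segs[i]
            for j in range(i + 1, len(segs)):
                gj, gj_end, aj, evj = segs[j]
                lo = max(ai, aj)
                hi = min(ai + (gi_end - gi), aj + (gj_end - gj))
                if hi <= lo:
                    continue
                a_iv = (gi + lo - ai, gi + hi - ai)
                b_iv = (gj + lo - aj, gj + hi - aj)
                if a_iv > b_iv:
                    a_iv, b_iv = b_iv, a_iv
                pairs.append((a_iv[0], a_iv[1], b_iv[0], b_iv[1],
                              min(evi, evj)))
        return pairs

    def alignment_pairs(self, min_len=1000):
        """Merged colinear homology pairs of length >= min_len, in global
        coordinates: (a_start, a_end, b_start, b_end, oldest_event)."""
        groups = {}
        for a0, a1, b0, b1, ev in self._raw_alignment_pairs():
            groups.setdefault(b0 - a0, []).append((a0, a1, ev))
        merged = []
        for offset, items in groups.items():
            items = sorted(items)
            cur = None
            for a0, a1, ev in items:
                if cur is None:
                    cur = [a0, a1, ev]
                elif a0 <= cur[1]:  # overlapping or touching: colinear run
                    cur[1] = max(cur[1], a1)
                    cur[2] = min(cur[2], ev)
                else:
                    merged.append((cur[0], cur[1], offset, cur[2]))
                    cur = [a0, a1, ev]
            if cur is not None:
                merged.append((cur[0], cur[1], offset, cur[2]))
        out = []
        for a0, a1, offset, ev in merged:
            if a1 - a0 >= min_len:
                out.append((a0, a1, a0 + offset, a1 + offset, ev))
        return sorted(out)

    def _identity_value(self, event: int, decay: float) -> float:
        n = max(len(self.events), 1)
        age = (len(self.events) - event) / n
        return 1.0 - decay * age

    def alignments(self, min_len=1000, identity_decay=0.08):
        """Emitted SD alignment records (the generator's table output)."""
        records = []
        for a0, a1, b0, b1, ev in self.alignment_pairs(min_len=min_len):
            ca, pa = self.to_chrom(a0)
            cb, pb = self.to_chrom(b0)
            records.append(SDAlignment(
                chrom_a=ca, start_a=pa, end_a=pa + (a1 - a0),
                chrom_b=cb, start_b=pb, end_b=pb + (b1 - b0),
                identity=self._identity_value(ev, identity_decay),
                aln_length=a1 - a0,
            ))
        return records

    def write_sedef_table(self, path, min_len=1000, identity_decay=0.08):
        """Write the emitted alignments as a SEDEF-style BEDPE table."""
        with open(path, "w") as fh:
            for aln in self.alignments(min_len=min_len,
                                       identity_decay=identity_decay):
                fh.write(f"{aln.chrom_a}\t{aln.start_a}\t{aln.end_a}\t"
                         f"{aln.chrom_b}\t{aln.start_b}\t{aln.end_b}\t"
                         f"{aln.identity:.4f}\n")

    # -- copy number -------------------------------------------------------
    def _ancestral_cn_prefix(self) -> np.ndarray:
        """Prefix sums of the per-base copy number in ancestral space."""
        total = self.n_chroms * self.chrom_len
        delta = np.zeros(total + 1, dtype=np.int64)
        delta[0] += 1
        delta[total] -= 1
        for g0, g1, a0, _ev in self.copy_segments:
            delta[a0] += 1
            delta[a0 + (g1 - g0)] -= 1
        cn = np.cumsum(delta[:-1])
        prefix = np.zeros(total + 1, dtype=np.int64)
        np.cumsum(cn, out=prefix[1:])
        return prefix

    def mean_copy_number(self, intervals) -> np.ndarray:
        """Mean per-base copy number of each (chrom, start, end) interval.

        A base's copy number is 1 + the number of extra copies of its
        ancestral base anywhere in the genome.
        """
        prefix = self._ancestral_cn_prefix()
        copies = sorted(self.copy_segments)

        def range_sum(a0, a1):
            return int(prefix[a1] - prefix[a0])

        out = np.empty(len(intervals), dtype=float)
        for k, (chrom, start, end) in enumerate(intervals):
            g0 = self.to_global(chrom, start)
            g1 = g0 + (end - start)
            total = 0
            pos = g0
            for c0, c1, a0, _ev in copies:
                if c1 <= pos or c0 >= g1:
                    continue
                if c0 > pos:  # original stretch before this copy
                    total += range_sum(pos, min(c0, g1))
                    pos = c0
                lo, hi = max(c0, pos), min(c1, g1)
                if hi > lo:
                    total += range_sum(a0 + (lo - c0), a0 + (hi - c0))
                    pos = hi
            if pos < g1:
                total += range_sum(pos, g1)
            out[k] = total / (end - start)
        return out

    @property
    def total_event_length(self) -> int:
        return sum(ev.length for ev in self.events)


# ---------------------------------------------------------------------------
# history simulation
# ---------------------------------------------------------------------------

def _merge_mark(identity_segments, start, end, event):
    """Insert an identity run, merging with overlapping/touching runs."""
    keep = []
    ev = event
    for s, e, sev in identity_segments:
        if e < start or s > end:  # disjoint, not even touching
            keep.append((s, e, sev))
        else:
            start, end = min(start, s), max(end, e)
            ev = min(ev, sev)
    keep.append((start, end, ev))
    keep.sort()
    return keep


def simulate_duplication_history(
    n_chroms=4,
    chrom_len=1_000_000,
    n_events=100,
    source_mode="uniform",
    pref_prob=0.7,
    len_range=(1_000, 100_000),
    insert_spacer=1_000,
    material_fraction=0.5,
    seed=None,
) -> SimulatedHistory:
    """Simulate a copy–paste duplication history.

    Each chromosome starts with ``material_fraction`` of its length as
    original sequence; the remainder is reserved empty space consumed by
    insertions (separated by ``insert_spacer`` bp so copies never touch by
    accident).  Source lengths are log-uniform on ``len_range``.  In
    ``preferential`` mode each event, with probability ``pref_prob``,
    anchors its source inside the already-duplicated footprint (chosen
    proportionally to footprint length), emulating duplication rates that
    grow with copy number; otherwise the source is uniform over all
    existing sequence.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if source_mode not in ("uniform", "preferential"):
        raise ValueError(f"unknown source_mode: {source_mode!r}")
    if len_range[0] < 1_000:
        raise ValueError("source lengths below 1 kbp are not detectable "
                         "as segmental duplications")
    rng = np.random.default_rng(seed)
    original_len = int(chrom_len * material_fraction)
    hist = SimulatedHistory(n_chroms=n_chroms, chrom_len=chrom_len,
                            original_len=original_len)

    # material blocks (existing sequence) and per-chromosome bump allocators
    material = [(i * chrom_len, i * chrom_len + original_len)
                for i in range(n_chroms)]
    alloc = [i * chrom_len + original_len for i in range(n_chroms)]

    def footprint():
        ivs = [(s, e) for s, e, _ in hist.identity_segments]
        ivs += [(s, e) for s, e, _a, _ev in hist.copy_segments]
        if not ivs:
            return []
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [tuple(iv) for iv in merged]

    def pick_uniform_source(length):
        weights = np.array([max(e - s - length + 1, 0) for s, e in material],
                           dtype=float)
        if weights.sum() == 0:
            length = max(min(e - s for s, e in material), 1)
            weights = np.array([max(e - s - length + 1, 0)
                                for s, e in material], dtype=float)
        block = material[rng.choice(len(material), p=weights / weights.sum())]
        start = int(rng.integers(block[0], block[1] - length + 1))
        return start, length

    def pick_preferential_source(length):
        fp = footprint()
        if not fp:
            return pick_uniform_source(length)
        lens = np.array([e - s for s, e in fp], dtype=float)
        s, e = fp[rng.choice(len(fp), p=lens / lens.sum())]
        anchor = int(rng.integers(s, e))
        block = next(b for b in material if b[0] <= anchor < b[1])
        length = min(length, block[1] - block[0])
        lo = max(block[0], anchor - length + 1)
        hi = min(anchor, block[1] - length)
        start = int(rng.integers(lo, hi + 1)) if hi >= lo else block[0]
        return start, length

    def resolve(start, end):
        """Split [start, end) into ancestry runs (off, length, astart, ev);
        original parts resolve to themselves with the current event index."""
        runs = []
        pos = start
        for c0, c1, a0, ev in sorted(hist.copy_segments):
            if c1 <= pos or c0 >= end:
                continue
            if c0 > pos:
                runs.append((pos - start, c0 - pos, pos, None))
                pos = c0
            lo, hi = max(c0, pos), min(c1, end)
            runs.append((lo - start, hi - lo, a0 + (lo - c0), ev))
            pos = hi
        if pos < end:
            runs.append((pos - start, end - pos, pos, None))
        return runs

    log_lo, log_hi = np.log(len_range[0]), np.log(len_range[1])
    for idx in range(n_events):
        length = int(np.exp(rng.uniform(log_lo, log_hi)))
        preferential = (source_mode == "preferential"
                        and rng.random() < pref_prob)
        if preferential:
            src, length = pick_preferential_source(length)
        else:
            src, length = pick_uniform_source(length)

        # allocate an insertion locus from the reserved empty space
        order = rng.permutation(n_chroms)
        dest = None
        for ci in order:
            if alloc[ci] + length <= (ci + 1) * chrom_len:
                dest = alloc[ci]
                alloc[ci] = dest + length + insert_spacer
                break
        if dest is None:
            raise RuntimeError("genome exhausted: no empty locus can hold "
                               f"a {length} bp insertion")

        for off, runlen, astart, ev in resolve(src, src + length):
            if ev is None:  # original sequence: becomes an identity anchor
                hist.identity_segments = _merge_mark(
                    hist.identity_segments, astart, astart + runlen, idx)
                hist.copy_segments.append((dest + off, dest + off + runlen,
                                           astart, idx))
            else:
                hist.copy_segments.append((dest + off, dest + off + runlen,
                                           astart, idx))
        material.append((dest, dest + length))
        material.sort()

        sc, sp = hist.to_chrom(src)
        dc, dp = hist.to_chrom(dest)
        hist.events.append(DuplicationEvent(
            index=idx, source_chrom=sc, source_start=sp,
            source_end=sp + length, insert_chrom=dc, insert_start=dp,
            preferential=preferential))
    return hist


# ---------------------------------------------------------------------------
# event-log oracle network
# ---------------------------------------------------------------------------

def ground_truth_network(hist: SimulatedHistory, min_len=1000) -> nx.Graph:
    """SD network derived directly from the event bookkeeping.

    Homology pairs of length >= ``min_len`` are read off the ancestry
    segments; their sides are clustered into regions by a brute-force
    pairwise-overlap closure (union–find), bypassing the alignment table
    and the sweep merge of the construction pipeline.  Nodes carry
    ``chrom``/``start``/``end`` attributes; node ids are assigned in
    (chrom, start) order.
    """
    pairs = hist.alignment_pairs(min_len=min_len)
    sides = []
    for a0, a1, b0, b1, _ev in pairs:
        sides.append((a0, a1))
        sides.append((b0, b1))
    if not sides:
        return nx.Graph()

    parent = list(range(len(sides)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    chrom_of = [hist.to_chrom(s)[0] for s, _ in sides]
    for i in range(len(sides)):
        for j in range(i + 1, len(sides)):
            if chrom_of[i] != chrom_of[j]:
                continue
            if sides[i][0] < sides[j][1] and sides[j][0] < sides[i][1]:
                union(i, j)

    clusters = {}
    for i in range(len(sides)):
        clusters.setdefault(find(i), []).append(i)
    bounds = {}
    for root, members in clusters.items():
        start = min(sides[i][0] for i in members)
        end = max(sides[i][1] for i in members)
        bounds[root] = (start, end)
    ordered = sorted(bounds.items(), key=lambda kv: kv[1])
    node_of_root = {root: k for k, (root, _b) in enumerate(ordered)}

    g = nx.Graph()
    for root, (start, end) in ordered:
        chrom, s = hist.to_chrom(start)
        g.add_node(node_of_root[root], chrom=chrom, start=s,
                   end=s + (end - start))
    for k in range(len(pairs)):
        na = node_of_root[find(2 * k)]
        nb = node_of_root[find(2 * k + 1)]
        if na != nb:
            g.add_edge(na, nb)
    return g


# ---------------------------------------------------------------------------
# synthetic CNV tables
# ---------------------------------------------------------------------------

def simulate_cnv_table(regions, n_cnvs, degree_effect=0.0, seed=None,
                       chrom_sizes=None, cohort_n=2504, base_p=0.5,
                       region_prob=0.6, len_range=(1_000, 50_000)):
    """CNV records whose minor-allele-count distribution depends on the
    degree of the duplicated regions they overlap.

    ``regions`` is an iterable of ``(chrom, start, end, degree)``.  Each
    CNV is centered on a random region with probability ``region_prob``
    (uniform over regions), otherwise placed uniformly on the genome.  Its
    MAC is geometric with success probability
    ``base_p / (1 + degree_effect * log(1 + d))`` where ``d`` is the
    largest degree among overlapped regions, so a positive
    ``degree_effect`` shifts mass toward high MACs in high-degree regions
    and ``degree_effect = 0`` is degree-blind.
    """
    if degree_effect < 0:
        raise ValueError("degree_effect must be >= 0")
    rng = np.random.default_rng(seed)
    regions = list(regions)
    if chrom_sizes is None:
        chrom_sizes = {}
        for chrom, start, end, _d in regions:
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), end)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)

    from intervaltree import IntervalTree
    trees = {}
    for chrom, start, end, degree in regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, degree)

    records = []
    for _ in range(int(n_cnvs)):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        if regions and rng.random() < region_prob:
            chrom, rstart, rend, _d = regions[rng.integers(len(regions))]
            center = int(rng.integers(rstart, rend))
        else:
            chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
            center = int(rng.integers(0, chrom_sizes[chrom]))
        start = max(0, center - length // 2)
        end = min(chrom_sizes[chrom], start + length)
        if end <= start:
            continue
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        degree = max((iv.data for iv in hits), default=0)
        p = base_p / (1.0 + degree_effect * np.log1p(degree))
        mac = int(min(cohort_n, rng.geometric(p)))
        records.append(CNVRecord(chrom, start, end, mac))
    return records
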