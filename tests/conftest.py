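import numpy as np
import pytest

from sdnet import (
    SDAlignment,
    build_network,
    merge_to_regions,
    simulate_duplication_history,
)


@pytest.fixture
def toy_alignments():
    """Two alignments producing three regions on two chromosomes:
    A: chr1:100-2100 <-> chr1:5000-7000, B: chr1:1500-2600 <-> chr2:100-1200.
    Sides chr1:100-2100 and chr1:1500-2600 overlap and merge."""
    return [
        SDAlignment("chr1", 100, 2100, "chr1", 5000, 7000, 0.95, 2000),
        SDAlignment("chr1", 1500, 2600, "chr2", 100, 1200, 0.93, 1100),
    ]


@pytest.fixture
def toy_network(toy_alignments):
    regions, side_to_region = merge_to_regions(toy_alignments)
    return build_network(regions, side_to_region, toy_alignments)


@pytest.fixture(scope="session")
def small_history():
    """A modest preferential-mode duplication history reused across tests."""
    return simulate_duplication_history(
        n_chroms=4, chrom_len=1_000_000, n_events=120,
        source_mode="preferential", seed=20240901)


def brute_force_regions(intervals):
    """O(n^2) transitive closure of >=1 bp interval overlap; the oracle for
    merge_to_regions.  ``intervals`` are (chrom, start, end)."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out = set()
    for members in clusters.values():
        chrom = intervals[members[0]][0]
        start = min(intervals[i][1] for i in members)
        end = max(intervals[i][2] for i in members)
        out.add((chrom, start, end))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
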