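"""CNV fixation analysis: variant frequency as a function of node degree.

Copy-number variants (CNVs) observed across a diploid cohort (2504
individuals in the reference data set) are split by minor allele count
(MAC) into rare [1, 3], medium [4, 15] and high [16, 2504] frequency
classes.  Duplicated regions are split by node degree into the bins
[1, 1], [2, 5], [6, 30] and [31, 140].  For each region class the table
reports the fraction of overlapping CNVs in each frequency class; CNVs
overlapping no duplicated region populate the "not_duplicated" row.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "MAC_BINS",
    "DEGREE_BINS",
    "classify_cnv",
    "classify_region",
    "overlap_fraction_table",
]

MAC_BINS = {"rare": (1, 3), "medium": (4, 15), "high": (16, 2504)}
DEGREE_BINS = [(1, 1), (2, 5), (6, 30), (31, 140)]
COHORT_MAX_MAC = 2504

_DEGREE_LABELS = [f"degree_{lo}_{hi}" for lo, hi in DEGREE_BINS]
NOT_DUPLICATED = "not_duplicated"


def classify_cnv(mac: int) -> str:
    """Frequency class of a CNV from its minor allele count (inclusive
    bounds)."""
    if mac < 1:
        raise ValueError("MAC must be >= 1")
    if mac > COHORT_MAX_MAC:
        raise ValueError(f"MAC {mac} exceeds the cohort bound "
                         f"{COHORT_MAX_MAC}")
    for label, (lo, hi) in MAC_BINS.items():
        if lo <= mac <= hi:
            return label
    raise AssertionError("unreachable")


def classify_region(degree: int) -> int:
    """Degree-bin index (0-based) of a duplicated region.

    Degrees above the top bin (the maximum observed in the reference
    network is 140) are assigned to the top bin with a warning.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1 for a duplicated region")
    for i, (lo, hi) in enumerate(DEGREE_BINS):
        if lo <= degree <= hi:
            return i
    warnings.warn(f"degree {degree} above the top bin; assigning to "
                  f"{DEGREE_BINS[-1]}")
    return len(DEGREE_BINS) - 1


def overlap_fraction_table(regions, cnvs) -> pd.DataFrame:
    """CNV frequency-class fractions per region-degree class.

    Parameters
    ----------
    regions : iterable of (chrom, start, end, degree)
        Duplicated regions with their node degrees.
    cnvs : iterable of CNVRecord (or (chrom, start, end, mac) tuples)

    A CNV overlaps a region class when it shares at least one bp with any
    region of that class; it is counted once per class but may count in
    several classes.  CNVs overlapping no region count in the
    ``not_duplicated`` row.  Rows are fractions over the row's CNV count
    (NaN where a class has no overlapping CNV); a ``n_cnvs`` column keeps
    the counts.
    """
    trees = {}
    for chrom, start, end, degree in regions:
        trees.setdefault(chrom, IntervalTree()).addi(
            start, end, classify_region(degree))

    rows = _DEGREE_LABELS + [NOT_DUPLICATED]
    counts = pd.DataFrame(0, index=rows,
                          columns=list(MAC_BINS), dtype=float)
    any_cnv = False
    for cnv in cnvs:
        any_cnv = True
        chrom, start, end, mac = (cnv.chrom, cnv.start, cnv.end, cnv.mac) \
            if hasattr(cnv, "mac") else cnv
        freq_class = classify_cnv(mac)
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        bins = {iv.data for iv in hits}
        if bins:
            for b in bins:
                counts.loc[_DEGREE_LABELS[b], freq_class] += 1
        else:
            counts.loc[NOT_DUPLICATED, freq_class] += 1
    if not any_cnv:
        warnings.warn("empty CNV set; table is undefined")
        counts[:] = np.nan

    totals = counts.sum(axis=1)
    fractions = counts.div(totals.replace(0, np.nan), axis=0)
    fractions["n_cnvs"] = totals
    return fractions
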