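"""Interval algebra used by every analysis stage.

Merging and coverage are implemented directly on sorted numpy arrays: the
pipeline issues coverage queries for millions of fixed-width windows, which
a prefix-sum representation of the merged interval set answers in O(log n)
each (vectorised over whole query arrays).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

from .types import BinPair, GenomicInterval

ALU_GROUPS = ("AluJ", "AluS", "AluY")


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals on one chromosome.

    Returns a sorted, pairwise-disjoint list covering exactly the union of
    the input bases. Abutting intervals (end == next start) are merged.
    """
    ivs = list(intervals)
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) != 1:
        raise ValueError(f"mixed chromosomes in merge_intervals: {sorted(chroms)}")
    chrom = ivs[0].chrom
    starts, ends = merge_arrays(
        np.array([iv.start for iv in ivs], dtype=np.int64),
        np.array([iv.end for iv in ivs], dtype=np.int64),
    )
    return [
        GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
    ]


def merge_arrays(
    starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge interval arrays (one chromosome) into disjoint sorted arrays."""
    if starts.size == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    # running maximum of ends; a new block starts where start > max(prev ends)
    run_max = np.maximum.accumulate(e)
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > run_max[:-1]
    block = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    # reduceat gives max end per block, which with the running max equals
    # the block's merged end
    assert out_s.size == block[-1] + 1
    return out_s, out_e


class CoverageIndex:
    """Prefix-sum index over a merged interval set on one chromosome.

    ``covered(a, b)`` returns the number of bases of ``[a, b)`` inside the
    union of the indexed intervals; the vectorised form accepts arrays.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts, self.ends = merge_arrays(
            np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)
        )
        lens = self.ends - self.starts
        self.cum = np.concatenate(([0], np.cumsum(lens)))

    @classmethod
    def from_intervals(cls, intervals: Sequence[GenomicInterval]) -> "CoverageIndex":
        return cls(
            np.array([iv.start for iv in intervals], dtype=np.int64),
            np.array([iv.end for iv in intervals], dtype=np.int64),
        )

    def _covered_below(self, x: np.ndarray) -> np.ndarray:
        """Total covered bases in [0, x) for each x."""
        idx = np.searchsorted(self.starts, x, side="right")
        total = self.cum[idx]
        # subtract the part of the last interval that extends past x
        has_prev = idx > 0
        prev = np.maximum(idx - 1, 0)
        overhang = np.where(
            has_prev, np.maximum(self.ends[prev] - x, 0), 0
        )
        # overhang can't exceed the last interval's length
        last_len = np.where(has_prev, self.ends[prev] - self.starts[prev], 0)
        return total - np.minimum(overhang, last_len)

    def covered(self, a, b):
        """Covered bases of [a, b); scalar or elementwise on arrays."""
        a_arr = np.atleast_1d(np.asarray(a, dtype=np.int64))
        b_arr = np.atleast_1d(np.asarray(b, dtype=np.int64))
        out = self._covered_below(b_arr) - self._covered_below(a_arr)
        if np.isscalar(a) or (isinstance(a, (int, np.integer))):
            return int(out[0])
        return out


def region_coverage(
    intervals: Iterable[GenomicInterval], region: GenomicInterval
) -> tuple[int, float]:
    """Bases of ``region`` covered by the union of ``intervals`` and the
    covered fraction of the region length."""
    same = [
        iv for iv in intervals if iv.chrom == region.chrom
    ]
    if not same:
        return 0, 0.0
    idx = CoverageIndex.from_intervals(same)
    bases = idx.covered(region.start, region.end)
    return bases, bases / len(region)


def binpair_region(pair: BinPair) -> tuple[GenomicInterval, GenomicInterval]:
    """The two fixed-width bin intervals of a contact pair."""
    if pair.start_i >= pair.start_j:
        raise ValueError("start_i must be < start_j")
    return (
        GenomicInterval(pair.chrom, pair.start_i, pair.start_i + pair.bin_size),
        GenomicInterval(pair.chrom, pair.start_j, pair.start_j + pair.bin_size),
    )


def subfamily_group(subfamily: str) -> str:
    """Map a repeat name to its Alu age group (AluJ/AluS/AluY) or 'other'.

    Longest-prefix match: AluYb8 -> AluY, AluSx1 -> AluS, FLAM/MIRb -> other.
    """
    if not subfamily:
        raise ValueError("empty subfamily name")
    for group in ALU_GROUPS:
        if subfamily.startswith(group):
            return group
    return "other"
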