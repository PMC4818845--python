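"""Stratification of bin-pairs by topological domain and frequency filtering.

A pair is *intra-domain* when both of its 40-kb bins lie fully inside one
common domain; *non-intra* when both bins lie inside (different) domains;
*boundary* when either bin is not fully contained in any domain. Boundary
pairs are excluded from all downstream statistics.

The lower frequency threshold is the arithmetic mean of the non-intra
stratum's frequencies (false-positive noise floor); the upper threshold is
the left edge of the first empty unit-width histogram window of the intra
frequencies (outlier cut).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .types import BinPair, Domain

logger = logging.getLogger(__name__)

INTRA, NON_INTRA, BOUNDARY = "intra", "non_intra", "boundary"


def validate_domains(domains: list[Domain]) -> dict:
    """Check per-chromosome non-overlap; return sorted (starts, ends) arrays."""
    by_chrom: dict[str, list] = {}
    for d in domains:
        by_chrom.setdefault(d.interval.chrom, []).append(d.interval)
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping domains on {chrom}")
        index[chrom] = (starts, ends)
    return index


def _containing_domain(index, chrom: str, start: int, end: int) -> int:
    """Index of the domain fully containing [start, end), or -1."""
    if chrom not in index:
        return -1
    starts, ends = index[chrom]
    k = int(np.searchsorted(starts, start, side="right")) - 1
    if k >= 0 and starts[k] <= start and end <= ends[k]:
        return k
    return -1


def classify_binpairs(
    pairs: list[BinPair], domains: list[Domain]
) -> list[str]:
    """Stratum label (intra / non_intra / boundary) per input pair."""
    index = validate_domains(domains)
    labels = []
    missing_chroms = set()
    for p in pairs:
        if p.chrom not in index:
            missing_chroms.add(p.chrom)
            labels.append(BOUNDARY)
            continue
        di = _containing_domain(index, p.chrom, p.start_i, p.start_i + p.bin_size)
        dj = _containing_domain(index, p.chrom, p.start_j, p.start_j + p.bin_size)
        if di < 0 or dj < 0:
            labels.append(BOUNDARY)
        elif di == dj:
            labels.append(INTRA)
        else:
            labels.append(NON_INTRA)
    if missing_chroms:
        logger.warning(
            "pairs on chromosomes absent from the domain set -> boundary: %s",
            sorted(missing_chroms),
        )
    return labels


def mean_interdomain_frequency(non_intra_pairs: list[BinPair]) -> float:
    """Arithmetic mean frequency of the non-intra stratum (lower threshold)."""
    if not non_intra_pairs:
        raise ValueError("cannot derive a lower threshold from an empty stratum")
    return float(np.mean([p.frequency for p in non_intra_pairs]))


def detect_upper_threshold(frequencies, step: float = 1.0) -> float:
    """Left edge of the first empty frequency-histogram window.

    Windows ``[k, k+step)`` are scanned upward from ``floor(min)``; if no
    window below the maximum is empty, ``floor(max) + step`` is returned.
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency collection")
    if step <= 0:
        raise ValueError("step must be positive")
    k0 = math.floor(freqs.min())
    idx = np.unique(((freqs - k0) // step).astype(np.int64))
    # first missing window index below the occupied maximum
    expected = np.arange(idx.size)
    gaps = np.flatnonzero(idx != expected)
    if gaps.size:
        return float(k0 + expected[gaps[0]] * step)
    return float(math.floor(freqs.max()) + step)


@dataclass
class FilterResult:
    retained: list = field(default_factory=list)
    removed_low_count: int = 0
    removed_high_count: int = 0
    removed_high_fraction: float = 0.0  # relative to pairs >= lower ("valid")


def filter_binpairs(pairs: list[BinPair], lower: float, upper: float) -> FilterResult:
    """Keep pairs with ``lower <= frequency < upper``; account for removals.

    The removed-high fraction is reported relative to the pairs surviving
    the lower threshold (the "valid" pairs).
    """
    if lower >= upper:
        raise ValueError(f"lower threshold {lower} must be < upper {upper}")
    res = FilterResult()
    n_valid = 0
    for p in pairs:
        if p.frequency < lower:
            res.removed_low_count += 1
            continue
        n_valid += 1
        if p.frequency >= upper:
            res.removed_high_count += 1
        else:
            res.retained.append(p)
    res.removed_high_fraction = (
        res.removed_high_count / n_valid if n_valid else 0.0
    )
    return res


@dataclass
class StratifiedBinPairs:
    """The three strata plus the thresholds derived from this run.

    ``intra`` holds only the retained pairs (lower <= f < upper); the
    removal counts account for the rest of the intra stratum.
    """

    intra: list
    non_intra: list
    boundary: list
    lower_threshold: float
    upper_threshold: float
    removed_low_count: int
    removed_high_count: int
    removed_high_fraction: float

    @property
    def n_input(self) -> int:
        return (
            len(self.intra) + self.removed_low_count + self.removed_high_count
            + len(self.non_intra) + len(self.boundary)
        )


def stratify_and_filter(
    pairs: list[BinPair], domains: list[Domain], step: float = 1.0
) -> StratifiedBinPairs:
    """Full filtering stage: classify, derive both thresholds, filter intra."""
    labels = classify_binpairs(pairs, domains)
    intra = [p for p, l in zip(pairs, labels) if l == INTRA]
    non_intra = [p for p, l in zip(pairs, labels) if l == NON_INTRA]
    boundary = [p for p, l in zip(pairs, labels) if l == BOUNDARY]
    if not intra:
        raise ValueError("no intra-domain pairs to filter")
    lower = mean_interdomain_frequency(non_intra)
    upper = detect_upper_threshold([p.frequency for p in intra], step=step)
    res = filter_binpairs(intra, lower, upper)
    return StratifiedBinPairs(
        intra=res.retained,
        non_intra=non_intra,
        boundary=boundary,
        lower_threshold=lower,
        upper_threshold=upper,
        removed_low_count=res.removed_low_count,
        removed_high_count=res.removed_high_count,
        removed_high_fraction=res.removed_high_fraction,
    )
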