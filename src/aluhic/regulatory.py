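"""Active enhancer / TSS calling and Alu-coverage enrichment analyses.

Active enhancers are the overlap regions of H3K4me1 and H3K27ac peaks;
active TSSs are TSS positions overlapped by H3K4me3 peaks (per gene the
TSS with the most supporting peaks wins). Element counts per bin-pair feed
the same binned-correlation machinery as the TE metrics; enhancers are
classified as Alu-derived by whether their reference point (summit, else
midpoint) lies inside an Alu copy, and their flanking Alu coverage is
compared against random genomic windows with a binomial (or permutation)
enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .enrichment import CorrelationResult, correlate_xy
from .intervals import CoverageIndex, merge_intervals
from .types import BinPair, GeneLocus, GenomicInterval, Peak

# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass
class EnhancerCall:
    """One maximal H3K4me1 ∩ H3K27ac overlap region."""

    interval: GenomicInterval
    origin: str | None = None  # "Alu_derived" | "non_Alu" once classified


@dataclass(frozen=True)
class ActiveTSS:
    chrom: str
    symbol: str
    position: int
    n_supporting_peaks: int
    strand: str

    def __post_init__(self):
        if self.n_supporting_peaks < 1:
            raise ValueError("an active TSS needs >= 1 supporting peak")


@dataclass(frozen=True)
class EnrichmentTestResult:
    n_windows: int
    k_above_background: int
    background_p0: float
    p_value: float
    method: str


@dataclass(frozen=True)
class MatchResult:
    """Mutual-nearest one-to-one peak matching between two sets."""

    shared: int
    fraction_a: float
    fraction_b: float


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p: float
    direction: int  # sign of (median active - median inactive)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def reference_point(element) -> int:
    """Summit when available, otherwise the interval midpoint."""
    rp = getattr(element, "reference_point", None)
    if rp is not None:
        return rp
    iv = element.interval if hasattr(element, "interval") else element
    return iv.midpoint


def alu_coverage_index(annotations) -> dict:
    """Per-chromosome CoverageIndex over the Alu copies of an annotation."""
    records = (
        annotations.annotations if hasattr(annotations, "annotations")
        else annotations
    )
    spans: dict[str, list] = {}
    for t in records:
        if t.family == "Alu":
            spans.setdefault(t.interval.chrom, []).append(
                (t.interval.start, t.interval.end)
            )
    return {
        chrom: CoverageIndex(
            np.array([s for s, _ in v], dtype=np.int64),
            np.array([e for _, e in v], dtype=np.int64),
        )
        for chrom, v in spans.items()
    }


def _intersect(a_list, b_list):
    """Intersection pieces of two disjoint sorted interval lists."""
    out = []
    i = j = 0
    while i < len(a_list) and j < len(b_list):
        a, b = a_list[i], b_list[j]
        lo, hi = max(a.start, b.start), min(a.end, b.end)
        if lo < hi:
            out.append(GenomicInterval(a.chrom, lo, hi))
        if a.end <= b.end:
            i += 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def deredundant_loci(genes: list[GeneLocus]) -> list[GeneLocus]:
    """One locus per symbol: the longest, ties broken by smaller start."""
    best: dict[str, GeneLocus] = {}
    for g in genes:
        cur = best.get(g.symbol)
        if cur is None:
            best[g.symbol] = g
            continue
        if (len(g.interval), -g.interval.start) > (
            len(cur.interval), -cur.interval.start
        ):
            best[g.symbol] = g
    return list(best.values())


def call_active_enhancers(
    me1_peaks: list[Peak], ac_peaks: list[Peak]
) -> list[EnhancerCall]:
    """Maximal disjoint H3K4me1 ∩ H3K27ac overlap regions."""
    by_chrom: dict[str, tuple[list, list]] = {}
    for p in me1_peaks:
        by_chrom.setdefault(p.interval.chrom, ([], []))[0].append(p.interval)
    for p in ac_peaks:
        by_chrom.setdefault(p.interval.chrom, ([], []))[1].append(p.interval)
    calls = []
    for chrom in sorted(by_chrom):
        me1, ac = by_chrom[chrom]
        if not me1 or not ac:
            continue
        pieces = _intersect(merge_intervals(me1), merge_intervals(ac))
        for iv in merge_intervals(pieces) if pieces else []:
            calls.append(EnhancerCall(interval=iv))
    return calls


def call_active_tss(
    genes: list[GeneLocus], me3_peaks: list[Peak]
) -> list[ActiveTSS]:
    """Per gene, the TSS with the most overlapping H3K4me3 peaks.

    A TSS is active when at least one peak covers its position. Ties are
    broken by larger summed peak signal, then by the 5'-most TSS
    (strand-aware). Genes without any active TSS are absent.
    """
    by_chrom: dict[str, list] = {}
    for p in me3_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    starts: dict[str, np.ndarray] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.interval.start)
        starts[chrom] = np.array([p.interval.start for p in plist], dtype=np.int64)
    out = []
    for gene in genes:
        chrom = gene.interval.chrom
        plist = by_chrom.get(chrom, [])
        best = None
        for tss in gene.tss_positions:
            n = 0
            signal = 0.0
            # peaks are short; scan the ones starting at or before the TSS
            hi = int(np.searchsorted(starts[chrom], tss, side="right")) if plist else 0
            for p in plist[:hi]:
                if p.interval.start <= tss < p.interval.end:
                    n += 1
                    signal += p.signal
            if n == 0:
                continue
            five_prime = -tss if gene.strand == "+" else tss
            key = (n, signal, five_prime)
            if best is None or key > best[0]:
                best = (key, tss, n)
        if best is not None:
            out.append(
                ActiveTSS(
                    chrom=chrom,
                    symbol=gene.symbol,
                    position=best[1],
                    n_supporting_peaks=best[2],
                    strand=gene.strand,
                )
            )
    return out


def _element_point(element):
    """Counting point of an element: position for points, midpoint for spans."""
    pos = getattr(element, "position", None)
    if pos is not None:
        return pos
    iv = element.interval if hasattr(element, "interval") else element
    return iv.midpoint


def count_in_binpair(elements, pair: BinPair) -> int:
    """Elements whose counting point lies in either of the pair's two bins."""
    n = 0
    for el in elements:
        chrom = getattr(el, "chrom", None)
        if chrom is None:
            iv = el.interval if hasattr(el, "interval") else el
            chrom = iv.chrom
        if chrom != pair.chrom:
            continue
        p = _element_point(el)
        if (
            pair.start_i <= p < pair.start_i + pair.bin_size
            or pair.start_j <= p < pair.start_j + pair.bin_size
        ):
            n += 1
    return n


@dataclass
class CoverageGroups:
    """Genome bins split into k equal-count groups by Alu coverage."""

    bins: list  # GenomicInterval per bin
    coverage: np.ndarray  # per-bin Alu coverage fraction
    assignment: np.ndarray  # per-bin group index, 0 = lowest coverage
    k: int

    @property
    def group_mean_coverage(self) -> np.ndarray:
        return np.array([
            self.coverage[self.assignment == g].mean() for g in range(self.k)
        ])


def group_bins_by_coverage(
    bins: list[GenomicInterval], alu_annotations, k: int = 5
) -> CoverageGroups:
    """Rank bins by Alu coverage into k equal-count groups.

    Remainder bins go to the lowest groups; ties are broken by genomic
    order (the ranking sort is stable over the input order).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(bins) < k:
        raise ValueError(f"need at least {k} bins, got {len(bins)}")
    cov_index = alu_coverage_index(alu_annotations)
    coverage = np.zeros(len(bins))
    for i, b in enumerate(bins):
        idx = cov_index.get(b.chrom)
        if idx is not None:
            coverage[i] = idx.covered(b.start, b.end) / len(b)
    order = np.argsort(coverage, kind="stable")
    n, base, rem = len(bins), len(bins) // k, len(bins) % k
    sizes = [base + (1 if g < rem else 0) for g in range(k)]
    assignment = np.empty(n, dtype=np.int64)
    pos = 0
    for g, size in enumerate(sizes):
        assignment[order[pos : pos + size]] = g
        pos += size
    return CoverageGroups(bins=bins, coverage=coverage, assignment=assignment, k=k)


def element_coverage_correlation(
    groups: CoverageGroups, elements
) -> CorrelationResult:
    """Pearson r over k points: group mean Alu coverage vs mean elements/bin."""
    if groups.k < 3:
        raise ValueError("need at least 3 groups for a correlation")
    # counting-point bin assignment
    counts = np.zeros(len(groups.bins))
    bin_lookup: dict[str, list] = {}
    for i, b in enumerate(groups.bins):
        bin_lookup.setdefault(b.chrom, []).append((b.start, b.end, i))
    starts_by_chrom = {
        c: (np.array([s for s, _, _ in v], dtype=np.int64), v)
        for c, v in (
            (c, sorted(v)) for c, v in bin_lookup.items()
        )
    }
    for el in elements:
        iv = el.interval if hasattr(el, "interval") else None
        chrom = iv.chrom if iv is not None else el.chrom
        p = _element_point(el)
        entry = starts_by_chrom.get(chrom)
        if entry is None:
            continue
        starts, rows = entry
        j = int(np.searchsorted(starts, p, side="right")) - 1
        if j >= 0 and rows[j][0] <= p < rows[j][1]:
            counts[rows[j][2]] += 1
    x = groups.group_mean_coverage
    y = np.array([
        counts[groups.assignment == g].mean() for g in range(groups.k)
    ])
    return correlate_xy(x, y, label="element_count_vs_alu_coverage")


def classify_enhancer_origin(enhancers, alu_annotations) -> list[str]:
    """"Alu_derived" iff the reference point lies inside an Alu copy.

    EnhancerCall objects get their ``origin`` field set in place.
    """
    cov = alu_coverage_index(alu_annotations)
    origins = []
    for el in enhancers:
        iv = el.interval if hasattr(el, "interval") else el
        idx = cov.get(iv.chrom)
        p = reference_point(el)
        inside = idx is not None and idx.covered(p, p + 1) == 1
        origin = "Alu_derived" if inside else "non_Alu"
        if isinstance(el, EnhancerCall):
            el.origin = origin
        origins.append(origin)
    return origins


def flank_coverage(
    elements, alu_annotations, flank: int = 20_000,
    chrom_sizes: dict | None = None,
) -> np.ndarray:
    """Alu coverage fraction of [ref - flank, ref + flank) per element,
    clipped to chromosome bounds when sizes are given."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    cov = alu_coverage_index(alu_annotations)
    out = np.zeros(len(elements))
    for i, el in enumerate(elements):
        iv = el.interval if hasattr(el, "interval") else el
        p = reference_point(el)
        lo = max(0, p - flank)
        hi = p + flank
        if chrom_sizes is not None:
            hi = min(hi, chrom_sizes[iv.chrom])
        idx = cov.get(iv.chrom)
        if idx is not None and hi > lo:
            out[i] = idx.covered(lo, hi) / (hi - lo)
    return out


def background_coverage(
    chrom_sizes: dict,
    alu_annotations,
    n_windows: int,
    width: int = 40_000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Alu coverage of seeded random fixed-width windows.

    Chromosomes are chosen proportional to length; windows lie fully inside
    their chromosome.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if width > lengths.max():
        raise ValueError("window width exceeds the longest chromosome")
    usable = np.array([chrom_sizes[c] >= width for c in chroms])
    weights = np.where(usable, lengths, 0.0)
    weights = weights / weights.sum()
    cov = alu_coverage_index(alu_annotations)
    picks = rng.choice(len(chroms), size=n_windows, p=weights)
    coverages = np.zeros(n_windows)
    for i, ci in enumerate(picks):
        chrom = chroms[ci]
        start = int(rng.integers(0, chrom_sizes[chrom] - width + 1))
        idx = cov.get(chrom)
        if idx is not None:
            coverages[i] = idx.covered(start, start + width) / width
    return coverages, float(coverages.mean())


def coverage_enrichment_test(
    observed: np.ndarray,
    background: np.ndarray,
    method: str = "binomial",
    seed: int = 0,
    n_permutations: int = 10_000,
) -> EnrichmentTestResult:
    """Is the observed windows' Alu coverage enriched over the background?

    binomial: success = an observed window's coverage exceeds the
    background mean; p0 = fraction of background windows exceeding their
    own mean; one-sided tail P(K >= k | n, p0).

    permutation: p = fraction of seeded size-n resamples of the background
    whose mean is >= the observed mean.
    """
    observed = np.asarray(observed, dtype=float)
    background = np.asarray(background, dtype=float)
    if observed.size == 0:
        raise ValueError("empty observed window set")
    if background.size == 0 or np.all(background == background[0]):
        raise ValueError("background must be non-degenerate")
    bg_mean = background.mean()
    n = observed.size
    k = int(np.count_nonzero(observed > bg_mean))
    p0 = float(np.count_nonzero(background > bg_mean) / background.size)
    if method == "binomial":
        p = float(stats.binom.sf(k - 1, n, p0))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        resamples = rng.choice(background, size=(n_permutations, n), replace=True)
        p = float(np.count_nonzero(resamples.mean(axis=1) >= observed.mean())
                  / n_permutations)
    else:
        raise ValueError("method must be 'binomial' or 'permutation'")
    return EnrichmentTestResult(
        n_windows=n, k_above_background=k, background_p0=p0,
        p_value=p, method=method,
    )


def match_peak_sets(set_a, set_b, max_dist: int = 250) -> MatchResult:
    """Mutual-nearest one-to-one matching of two peak sets.

    Two peaks are the "same" element when each is the other's nearest
    (same chromosome, reference-point distance strictly below max_dist).
    """
    def _points(peaks):
        by_chrom: dict[str, list] = {}
        for i, p in enumerate(peaks):
            iv = p.interval if hasattr(p, "interval") else p
            by_chrom.setdefault(iv.chrom, []).append((reference_point(p), i))
        return {
            c: (np.array(sorted(x for x, _ in v), dtype=np.int64),
                [i for x, i in sorted(v)])
            for c, v in by_chrom.items()
        }

    pa, pb = _points(set_a), _points(set_b)
    shared = 0
    for chrom in pa:
        if chrom not in pb:
            continue
        xa, _ = pa[chrom]
        xb, _ = pb[chrom]

        def nearest(src, dst):
            """index in dst of the nearest point per src point (tie: left)."""
            j = np.searchsorted(dst, src)
            left = np.maximum(j - 1, 0)
            right = np.minimum(j, dst.size - 1)
            dl = np.abs(src - dst[left])
            dr = np.abs(src - dst[right])
            return np.where(dl <= dr, left, right)

        a2b = nearest(xa, xb)
        b2a = nearest(xb, xa)
        mutual = b2a[a2b] == np.arange(xa.size)
        close = np.abs(xa - xb[a2b]) < max_dist
        shared += int(np.count_nonzero(mutual & close))
    return MatchResult(
        shared=shared,
        fraction_a=shared / len(set_a) if set_a else 0.0,
        fraction_b=shared / len(set_b) if set_b else 0.0,
    )


def compare_active_expression(
    expression: dict, active_symbols
) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum: active vs non-active gene expression."""
    active_set = set(active_symbols)
    active = [v for k, v in expression.items() if k in active_set]
    inactive = [v for k, v in expression.items() if k not in active_set]
    if not active or not inactive:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(active, inactive, alternative="two-sided")
    direction = int(np.sign(np.median(active) - np.median(inactive)))
    return RankSumResult(
        statistic=float(res.statistic), p=float(res.pvalue), direction=direction
    )
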