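"""Origin-partitioned GC / CpG / methylation accounting per bin-pair.

Every base of a bin-pair's combined region is assigned to exactly one of
three origin classes — ``Alu`` (bases covered by Alu-family SINE copies),
``SINE_non_Alu`` (bases covered by other SINE copies and not by Alu) and
``non_SINE`` (the remainder) — with precedence Alu > SINE_non_Alu where
annotations overlap. Per class the module counts bases, G/C bases, CpG
sites (a site belongs to the class of its C position) and methylated CpG
sites, and derives GC content, CpG density (CpG per G/C base), methylation
density (methylated fraction of CpG sites) and their correlations with
contact frequency.

Ambiguous bases (N) count toward class length but never toward GC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enrichment import bin_by_frequency, correlate_bins
from .intervals import binpair_region, merge_intervals, subfamily_group
from .types import BinPair, CpGSite, GenomicInterval

CLASSES = ("Alu", "SINE_non_Alu", "non_SINE")
_GC_BYTES = (ord("G"), ord("C"))


def _clip_merge(intervals, window: GenomicInterval):
    """Merged pieces of the intervals clipped to the window."""
    clipped = [
        GenomicInterval(
            window.chrom, max(iv.start, window.start), min(iv.end, window.end)
        )
        for iv in intervals
        if iv.chrom == window.chrom
        and iv.start < window.end
        and iv.end > window.start
    ]
    return merge_intervals(clipped)


def _subtract(a_list, b_list):
    """Merged pieces of a (disjoint sorted) not covered by b (disjoint sorted)."""
    out = []
    bi = 0
    for a in a_list:
        cur = a.start
        while bi < len(b_list) and b_list[bi].end <= cur:
            bi += 1
        k = bi
        while k < len(b_list) and b_list[k].start < a.end:
            b = b_list[k]
            if b.start > cur:
                out.append(GenomicInterval(a.chrom, cur, b.start))
            cur = max(cur, b.end)
            k += 1
            if cur >= a.end:
                break
        if cur < a.end:
            out.append(GenomicInterval(a.chrom, cur, a.end))
    return out


@dataclass
class OriginPartition:
    """Disjoint decomposition of a bin-pair's bases by repeat origin."""

    pair: BinPair
    classes: dict  # class name -> list[GenomicInterval], disjoint, sorted

    def class_length(self, cls: str) -> int:
        return sum(len(iv) for iv in self.classes[cls])


def partition_binpair(pair: BinPair, annotations) -> OriginPartition:
    """Partition the pair's two bins into the three origin classes."""
    records = (
        annotations.annotations if hasattr(annotations, "annotations")
        else annotations
    )
    sines = [
        t.interval for t in records
        if t.te_class == "SINE" and t.interval.chrom == pair.chrom
    ]
    alus = [
        t.interval for t in records
        if t.family == "Alu" and t.interval.chrom == pair.chrom
    ]
    out = {cls: [] for cls in CLASSES}
    for window in binpair_region(pair):
        alu_parts = _clip_merge(alus, window)
        sine_parts = _clip_merge(sines, window)
        non_alu_sine = _subtract(sine_parts, alu_parts)
        covered = merge_intervals(alu_parts + non_alu_sine) if (
            alu_parts or non_alu_sine
        ) else []
        rest = _subtract([window], covered)
        out["Alu"].extend(alu_parts)
        out["SINE_non_Alu"].extend(non_alu_sine)
        out["non_SINE"].extend(rest)
    return OriginPartition(pair=pair, classes=out)


@dataclass
class ClassCounts:
    total_len: int = 0
    gc_count: int = 0
    cpg_count: int = 0
    meth_cpg_count: int = 0


@dataclass
class CompositionSummary:
    """Per-class base/GC/CpG/methylation counts for one bin-pair."""

    pair: BinPair
    counts: dict = field(default_factory=dict)  # class -> ClassCounts

    def total(self, attr: str) -> int:
        return sum(getattr(c, attr) for c in self.counts.values())


class CpGTable:
    """Sorted per-chromosome view of a CpG call list for range queries."""

    def __init__(self, sites: list[CpGSite]):
        by_chrom: dict[str, list] = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append((s.pos, s.methylated))
        self.pos: dict[str, np.ndarray] = {}
        self.meth: dict[str, np.ndarray] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            p = np.array([r[0] for r in rows], dtype=np.int64)
            if np.any(p[1:] == p[:-1]):
                raise ValueError(f"duplicate CpG positions on {chrom}")
            self.pos[chrom] = p
            self.meth[chrom] = np.array([r[1] for r in rows], dtype=bool)

    def in_range(self, chrom: str, start: int, end: int):
        """(positions, methylated flags) of sites with C in [start, end)."""
        p = self.pos.get(chrom)
        if p is None:
            return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool))
        lo, hi = np.searchsorted(p, (start, end))
        return p[lo:hi], self.meth[chrom][lo:hi]


def _as_cpg_table(cpg_calls) -> CpGTable:
    return cpg_calls if isinstance(cpg_calls, CpGTable) else CpGTable(cpg_calls)


def composition_summary(
    genome: dict, partition: OriginPartition, cpg_calls
) -> CompositionSummary:
    """Count bases, G/C, CpG sites and methylated sites per origin class.

    ``genome`` maps chromosome name to sequence. A call whose position is
    not a CG dinucleotide in the sequence indicates an inconsistent bundle
    and raises.
    """
    table = _as_cpg_table(cpg_calls)
    chrom = partition.pair.chrom
    seq = genome[chrom]
    summary = CompositionSummary(pair=partition.pair)
    for cls in CLASSES:
        cc = ClassCounts()
        for iv in partition.classes[cls]:
            cc.total_len += len(iv)
            piece = seq[iv.start : iv.end].upper()
            cc.gc_count += piece.count("G") + piece.count("C")
            pos, meth = table.in_range(chrom, iv.start, iv.end)
            for p in pos:
                if seq[p : p + 2].upper() != "CG":
                    raise ValueError(
                        f"CpG call at {chrom}:{p} is not a CG dinucleotide"
                    )
            cc.cpg_count += int(pos.size)
            cc.meth_cpg_count += int(meth.sum())
        summary.counts[cls] = cc
    return summary


def gc_contribution(summary: CompositionSummary) -> tuple[dict, float]:
    """Per-class GC fraction of the whole region and their sum (background)."""
    region_len = summary.total("total_len")
    contributions = {
        cls: summary.counts[cls].gc_count / region_len for cls in CLASSES
    }
    return contributions, sum(contributions.values())


def cpg_density(summary: CompositionSummary, cls: str | None = None):
    """CpG sites per G/C base, per class or overall; None when undefined."""
    if cls is None:
        gc, cpg = summary.total("gc_count"), summary.total("cpg_count")
    else:
        gc, cpg = summary.counts[cls].gc_count, summary.counts[cls].cpg_count
    return None if gc == 0 else cpg / gc


def cpg_density_ratio(summary: CompositionSummary):
    """CpG density of Alu bases over the pooled non-Alu bases."""
    d_alu = cpg_density(summary, "Alu")
    gc = sum(summary.counts[c].gc_count for c in ("SINE_non_Alu", "non_SINE"))
    cpg = sum(summary.counts[c].cpg_count for c in ("SINE_non_Alu", "non_SINE"))
    if d_alu is None or gc == 0 or cpg == 0:
        return None
    return d_alu / (cpg / gc)


def methylation_density(summary: CompositionSummary, cls: str | None = None):
    """Methylated fraction of CpG sites, per class or overall; None if no sites."""
    if cls is None:
        cpg, meth = summary.total("cpg_count"), summary.total("meth_cpg_count")
    else:
        cpg = summary.counts[cls].cpg_count
        meth = summary.counts[cls].meth_cpg_count
    return None if cpg == 0 else meth / cpg


def subfamily_methylation(cpg_calls, annotations) -> dict:
    """Methylation density per Alu age group (AluJ/AluS/AluY).

    A site is assigned to the group of the Alu copy containing its C
    position; groups with no sites are omitted.
    """
    table = _as_cpg_table(cpg_calls)
    records = (
        annotations.annotations if hasattr(annotations, "annotations")
        else annotations
    )
    totals = {g: [0, 0] for g in ("AluJ", "AluS", "AluY")}
    by_chrom: dict[str, list] = {}
    for t in records:
        if t.family == "Alu":
            by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom, alus in by_chrom.items():
        if chrom not in table.pos:
            continue
        alus.sort(key=lambda t: t.interval.start)
        starts = np.array([t.interval.start for t in alus], dtype=np.int64)
        ends = np.array([t.interval.end for t in alus], dtype=np.int64)
        groups = np.array([subfamily_group(t.subfamily) for t in alus])
        pos = table.pos[chrom]
        meth = table.meth[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        for g in totals:
            sel = inside & (groups[np.maximum(idx, 0)] == g)
            totals[g][0] += int(sel.sum())
            totals[g][1] += int(meth[sel].sum())
    return {
        g: k / n for g, (n, k) in totals.items() if n > 0
    }


def estimate_methylation_rate(
    d_old: float, age_old: float, d_young: float, age_young: float
) -> float:
    """Methylation-density change per million years between two age groups."""
    if age_old == age_young:
        raise ValueError("ages must differ")
    return (d_old - d_young) / (age_old - age_young)


# ---------------------------------------------------------------------------
# bulk path: per-base arrays for whole-bundle correlation analysis
# ---------------------------------------------------------------------------

class GenomeComposition:
    """Per-chromosome base-level arrays for fast per-pair accounting.

    label: 2 = Alu, 1 = SINE_non_Alu, 0 = non_SINE (precedence applied);
    gc / cpg / meth are boolean masks (cpg and meth set at the C position).
    """

    def __init__(self, genome: dict, annotations, cpg_calls):
        records = (
            annotations.annotations if hasattr(annotations, "annotations")
            else annotations
        )
        table = _as_cpg_table(cpg_calls)
        self.label: dict[str, np.ndarray] = {}
        self.gc: dict[str, np.ndarray] = {}
        self.cpg: dict[str, np.ndarray] = {}
        self.meth: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            gc = (arr == _GC_BYTES[0]) | (arr == _GC_BYTES[1])
            label = np.zeros(arr.size, dtype=np.uint8)
            for t in records:
                iv = t.interval
                if iv.chrom != chrom or t.te_class != "SINE":
                    continue
                if t.family != "Alu":
                    label[iv.start : iv.end] = 1
            for t in records:
                iv = t.interval
                if iv.chrom == chrom and t.family == "Alu":
                    label[iv.start : iv.end] = 2
            cpg = np.zeros(arr.size, dtype=bool)
            meth = np.zeros(arr.size, dtype=bool)
            pos = table.pos.get(chrom)
            if pos is not None:
                if pos.size and pos[-1] >= arr.size - 1:
                    raise ValueError(f"CpG call beyond {chrom} end")
                is_cg = (arr[pos] == ord("C")) & (arr[pos + 1] == ord("G"))
                if not np.all(is_cg):
                    bad = int(pos[~is_cg][0])
                    raise ValueError(
                        f"CpG call at {chrom}:{bad} is not a CG dinucleotide"
                    )
                cpg[pos] = True
                meth[pos[table.meth[chrom]]] = True
            self.label[chrom] = label
            self.gc[chrom] = gc
            self.cpg[chrom] = cpg
            self.meth[chrom] = meth

    def pair_summary(self, pair: BinPair) -> CompositionSummary:
        """CompositionSummary for one pair from the base-level arrays."""
        chrom = pair.chrom
        sl = np.concatenate([
            self.label[chrom][pair.start_i : pair.start_i + pair.bin_size],
            self.label[chrom][pair.start_j : pair.start_j + pair.bin_size],
        ])
        masks = {"non_SINE": sl == 0, "SINE_non_Alu": sl == 1, "Alu": sl == 2}
        out = CompositionSummary(pair=pair)
        for cls, mask in masks.items():
            cc = ClassCounts(total_len=int(mask.sum()))
            for attr, store in (
                ("gc_count", self.gc), ("cpg_count", self.cpg),
                ("meth_cpg_count", self.meth),
            ):
                vals = np.concatenate([
                    store[chrom][pair.start_i : pair.start_i + pair.bin_size],
                    store[chrom][pair.start_j : pair.start_j + pair.bin_size],
                ])
                setattr(cc, attr, int(np.count_nonzero(vals & mask)))
            out.counts[cls] = cc
        return out


#: quantities reported by composition_vs_frequency
COMPOSITION_QUANTITIES = ("gc", "cpg_density", "cpg_share", "meth_density")


def composition_vs_frequency(
    pairs: list[BinPair],
    genome: dict,
    annotations,
    cpg_calls,
    n_bins: int = 50,
    comp: GenomeComposition | None = None,
) -> dict:
    """Binned correlation with frequency for every composition quantity.

    Returns {(quantity, class): CorrelationResult} where quantity is one of
    ``gc`` (per-class contribution to region GC, plus 'background' = total),
    ``cpg_density`` (per-class CpG per G/C, plus overall), ``cpg_share``
    (fraction of the pair's CpG sites of Alu origin) and ``meth_density``
    (per-class and overall methylated fraction). Pairs where a quantity is
    undefined (no G/C or no CpG in the class) are dropped for that quantity.
    """
    if comp is None:
        comp = GenomeComposition(genome, annotations, cpg_calls)
    freqs = np.array([p.frequency for p in pairs], dtype=float)
    values: dict[tuple, np.ndarray] = {}
    keys = (
        [("gc", "background")] + [("gc", c) for c in CLASSES]
        + [("cpg_density", "background")] + [("cpg_density", c) for c in CLASSES]
        + [("cpg_share", "Alu")]
        + [("meth_density", "background")] + [("meth_density", c) for c in CLASSES]
    )
    for key in keys:
        values[key] = np.full(len(pairs), np.nan)
    for k, pair in enumerate(pairs):
        s = comp.pair_summary(pair)
        region_len = s.total("total_len")
        contrib, background = gc_contribution(s)
        values[("gc", "background")][k] = background
        for c in CLASSES:
            values[("gc", c)][k] = contrib[c]
        d = cpg_density(s)
        if d is not None:
            values[("cpg_density", "background")][k] = d
        for c in CLASSES:
            d = cpg_density(s, c)
            if d is not None:
                values[("cpg_density", c)][k] = d
        total_cpg = s.total("cpg_count")
        if total_cpg:
            values[("cpg_share", "Alu")][k] = (
                s.counts["Alu"].cpg_count / total_cpg
            )
        m = methylation_density(s)
        if m is not None:
            values[("meth_density", "background")][k] = m
        for c in CLASSES:
            m = methylation_density(s, c)
            if m is not None:
                values[("meth_density", c)][k] = m
    out = {}
    for key, vals in values.items():
        ok = ~np.isnan(vals)
        if ok.sum() < 3:
            out[key] = None
            continue
        try:
            bins = bin_by_frequency(freqs[ok], vals[ok], n_bins)
            out[key] = correlate_bins(bins, label=f"{key[0]}:{key[1]}")
        except ValueError:
            out[key] = None
    return out
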