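"""Seeded synthetic input bundle with planted statistical structure.

The generator emulates, at desk scale, the full input universe of the
analysis: a small multi-chromosome genome (FASTA), topological domains that
tile each chromosome, normalized 40-kb bin-pair contact frequencies with
distinct intra-/inter-domain distributions, RepeatMasker-style repeat
annotation in which Alu placement is linearly coupled to contact frequency,
a per-CpG methylome with subfamily-specific methylation rates, histone
peaks (H3K4me1/H3K27ac/H3K4me3) whose rates grow with contact frequency,
and a gene/TSS table. A truth manifest records every planted parameter so
recovery can be tested.

Generative model
----------------
Each 40-kb bin ``b`` carries a latent activity ``a_b ~ N(0, bin_activity_sd)``
shared by every pair that touches the bin. An intra-domain pair (i, j) at
genomic distance d megabases has frequency

    f_ij = intra_freq_base * exp(-decay * d + a_i + a_j + eps),
    eps ~ N(0, intra_freq_noise_sd),

while non-intra pairs draw from Exponential(inter_freq_mean). Alu copies
per bin are Poisson with mean ``alu_rate_intercept + alu_rate_slope * fbar_b``
where ``fbar_b`` is the bin's realized mean intra frequency, so Alu density
and contact frequency are positively coupled through the shared activity;
the other repeat families are placed at frequency-independent rates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import subfamily_group
from .io import write_fasta, write_records
from .types import (
    BinPair,
    CpGSite,
    Domain,
    GeneLocus,
    GenomicInterval,
    Peak,
    TEAnnotation,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G = ord("C"), ord("G")

# subfamily names drawn per Alu age group, and typical percent divergences
_ALU_NAMES = {
    "AluJ": ("AluJb", "AluJo", "AluJr"),
    "AluS": ("AluSx", "AluSg", "AluSp", "AluSq"),
    "AluY": ("AluY", "AluYa5", "AluYb8"),
}
_ALU_DIV = {"AluJ": 16.0, "AluS": 11.0, "AluY": 4.0}

# frequency-independent families: (te_class, family, subfamily names)
_OTHER_FAMILIES = {
    "L1": ("LINE", "L1", ("L1PA2", "L1PA7", "L1MB5")),
    "LTR": ("LTR", "ERVL", ("MLT1A", "MLT1B", "LTR16A")),
    "DNA": ("DNA", "hAT-Charlie", ("Charlie1", "MER5A", "Tigger1")),
    "MIR": ("SINE", "MIR", ("MIRb", "MIRc", "MIR3")),
}


@dataclass(frozen=True)
class SimConfig:
    """All planted parameters of the synthetic bundle (defaults = the
    study conditions the analysis is exercised under)."""

    n_chrom: int = 2
    chrom_length: int = 8_000_000
    bin_size: int = 40_000
    # domains: lognormal lengths snapped to the bin grid, tiling each chromosome
    domain_length_mean: float = 1_000_000.0
    domain_length_log_sd: float = 0.5
    # contact frequencies
    inter_freq_mean: float = 2.0
    intra_freq_base: float = 15.0
    intra_freq_decay: float = 0.8  # per megabase
    intra_freq_noise_sd: float = 0.5
    # log-activity shared by all pairs touching a bin; an optional
    # domain-level (compartment-like) component can be layered on top
    domain_activity_sd: float = 0.0
    bin_activity_sd: float = 0.5
    # Alu placement: Poisson(alu_rate_intercept + alu_rate_slope * mean bin freq)
    alu_rate_intercept: float = 2.0
    alu_rate_slope: float = 0.4
    alu_length_mean: float = 300.0
    alu_length_sd: float = 30.0
    alu_length_min: int = 50
    subfamily_mix: tuple[float, float, float] = (0.25, 0.55, 0.20)  # J, S, Y
    # frequency-independent families: copies per 40-kb bin and fragment
    # lengths, matched to human-genome RepeatMasker per-bin copy numbers
    l1_rate: float = 6.0
    l1_length_mean: float = 900.0
    l1_length_sd: float = 250.0
    ltr_rate: float = 9.0
    ltr_length_mean: float = 500.0
    ltr_length_sd: float = 150.0
    dna_rate: float = 6.0
    dna_length_mean: float = 250.0
    dna_length_sd: float = 80.0
    mir_rate: float = 7.0
    mir_length_mean: float = 180.0
    mir_length_sd: float = 40.0
    # sequence composition
    gc_background: float = 0.41
    gc_alu: float = 0.60
    cpg_rate_alu: float = 0.06
    cpg_rate_background: float = 0.01
    # methylation rates per context
    meth_rate: dict = field(
        default_factory=lambda: {
            "AluJ": 0.92,
            "AluS": 0.90,
            "AluY": 0.78,
            "promoter": 0.20,
            "gene_body": 0.70,
            "other": 0.75,
        }
    )
    # regulatory elements: Poisson(intercept + slope * mean bin freq) per bin
    enhancer_rate_intercept: float = 0.05
    enhancer_rate_slope: float = 0.03
    tss_rate_intercept: float = 0.05
    tss_rate_slope: float = 0.02
    enhancer_alu_fraction: float = 0.6  # prob. an enhancer centers inside an Alu
    genes_per_chrom: int = 60
    promoter_halfwidth: int = 1_000
    # bin-pair list construction
    max_near_distance: int = 2_000_000
    far_pair_fraction: float = 0.1
    liftover_drop_fraction: float = 0.0668
    seed: int = 0

    def __post_init__(self):
        rates = {
            "inter_freq_mean": self.inter_freq_mean,
            "intra_freq_base": self.intra_freq_base,
            "intra_freq_decay": self.intra_freq_decay,
            "intra_freq_noise_sd": self.intra_freq_noise_sd,
            "domain_activity_sd": self.domain_activity_sd,
            "bin_activity_sd": self.bin_activity_sd,
            "alu_rate_intercept": self.alu_rate_intercept,
            "alu_rate_slope": self.alu_rate_slope,
            "l1_rate": self.l1_rate,
            "ltr_rate": self.ltr_rate,
            "dna_rate": self.dna_rate,
            "mir_rate": self.mir_rate,
            "enhancer_rate_intercept": self.enhancer_rate_intercept,
            "enhancer_rate_slope": self.enhancer_rate_slope,
            "tss_rate_intercept": self.tss_rate_intercept,
            "tss_rate_slope": self.tss_rate_slope,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        probs = {
            "gc_background": self.gc_background,
            "gc_alu": self.gc_alu,
            "cpg_rate_alu": self.cpg_rate_alu,
            "cpg_rate_background": self.cpg_rate_background,
            "enhancer_alu_fraction": self.enhancer_alu_fraction,
            "far_pair_fraction": self.far_pair_fraction,
            "liftover_drop_fraction": self.liftover_drop_fraction,
            **{f"meth_rate[{k}]": v for k, v in self.meth_rate.items()},
            **{f"subfamily_mix[{i}]": v for i, v in enumerate(self.subfamily_mix)},
        }
        for name, value in probs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if abs(sum(self.subfamily_mix) - 1.0) > 1e-9:
            raise ValueError("subfamily_mix must sum to 1")
        if self.chrom_length % self.bin_size:
            raise ValueError("chrom_length must be a multiple of bin_size")


def default_config(overrides: dict | None = None) -> SimConfig:
    """Build a SimConfig from defaults plus a partial field mapping."""
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    if "subfamily_mix" in overrides:
        overrides["subfamily_mix"] = tuple(overrides["subfamily_mix"])
    return SimConfig(**overrides)


@dataclass
class TruthManifest:
    """Planted parameters of one realized bundle, for recovery tests."""

    config: SimConfig
    coupling_sign: dict  # family -> "+", "-" or "none"
    alu_copy_count: int
    realized_meth_rate: dict  # subfamily group -> realized methylated fraction
    expected_positive_metrics: list

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "coupling_sign": self.coupling_sign,
            "alu_copy_count": self.alu_copy_count,
            "realized_meth_rate": self.realized_meth_rate,
            "expected_positive_metrics": self.expected_positive_metrics,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        payload = json.loads(text)
        cfg = payload["config"]
        cfg["subfamily_mix"] = tuple(cfg["subfamily_mix"])
        return cls(
            config=SimConfig(**cfg),
            coupling_sign=payload["coupling_sign"],
            alu_copy_count=payload["alu_copy_count"],
            realized_meth_rate=payload["realized_meth_rate"],
            expected_positive_metrics=payload["expected_positive_metrics"],
        )


@dataclass
class Bundle:
    """In-memory synthetic bundle (what simulate_all writes to disk)."""

    config: SimConfig
    chrom_sizes: dict
    domains: list
    binpairs: list
    repeats: list
    genes: list
    peaks: dict  # mark -> list[Peak]
    genome: dict | None  # chrom -> sequence string
    cpg_sites: list
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# contact skeleton (shared with the Monte-Carlo band helper)
# ---------------------------------------------------------------------------

def _tile_domains(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    """Domain lengths (bases, bin-grid multiples) tiling one chromosome."""
    mu = np.log(cfg.domain_length_mean) - cfg.domain_length_log_sd**2 / 2
    lengths = []
    total = 0
    while total < cfg.chrom_length:
        raw = rng.lognormal(mu, cfg.domain_length_log_sd)
        snapped = max(cfg.bin_size, round(raw / cfg.bin_size) * cfg.bin_size)
        snapped = min(snapped, cfg.chrom_length - total)
        lengths.append(int(snapped))
        total += snapped
    return lengths


def _simulate_contacts(cfg: SimConfig, rng: np.random.Generator):
    """Domains, pair lists and frequencies for every chromosome.

    Returns a dict per chromosome with bin activities, pair index arrays
    (bin indices i < j), frequencies, intra flags and per-bin mean intra
    frequency ``fbar`` (bins with no intra pair fall back to the inter mean).
    """
    n_bins = cfg.chrom_length // cfg.bin_size
    out = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        dom_lengths = _tile_domains(cfg, rng)
        dom_starts = np.concatenate(([0], np.cumsum(dom_lengths)[:-1]))
        dom_ends = np.cumsum(dom_lengths)
        # a bin belongs to the domain containing its whole span
        bin_dom = np.searchsorted(dom_starts, np.arange(n_bins) * cfg.bin_size,
                                  side="right") - 1
        dom_effects = rng.normal(0.0, cfg.domain_activity_sd, len(dom_lengths))
        activities = (
            dom_effects[bin_dom] + rng.normal(0.0, cfg.bin_activity_sd, n_bins)
        )

        ii, jj = np.triu_indices(n_bins, k=1)
        dist = (jj - ii) * cfg.bin_size
        near = dist <= cfg.max_near_distance
        far_keep = rng.random(ii.size) < cfg.far_pair_fraction
        keep = near | far_keep
        ii, jj, dist = ii[keep], jj[keep], dist[keep]

        intra = bin_dom[ii] == bin_dom[jj]

        freq = np.empty(ii.size)
        d_mb = dist / 1e6
        eps = rng.normal(0.0, cfg.intra_freq_noise_sd, ii.size)
        intra_f = cfg.intra_freq_base * np.exp(
            -cfg.intra_freq_decay * d_mb + activities[ii] + activities[jj] + eps
        )
        inter_f = rng.exponential(cfg.inter_freq_mean, ii.size)
        freq = np.where(intra, intra_f, inter_f)

        fbar = np.full(n_bins, cfg.inter_freq_mean)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        np.add.at(sums, ii[intra], freq[intra])
        np.add.at(sums, jj[intra], freq[intra])
        np.add.at(counts, ii[intra], 1)
        np.add.at(counts, jj[intra], 1)
        touched = counts > 0
        fbar[touched] = sums[touched] / counts[touched]

        out[chrom] = {
            "dom_starts": dom_starts,
            "dom_ends": dom_ends,
            "activities": activities,
            "ii": ii,
            "jj": jj,
            "freq": freq,
            "intra": intra,
            "fbar": fbar,
        }
    return out


def _place_family(
    cfg: SimConfig,
    rng: np.random.Generator,
    chrom: str,
    per_bin_rate: np.ndarray,
    length_mean: float,
    length_sd: float,
    te_class: str,
    family: str,
    subfamily_names,
    subfamily_probs=None,
    divergence_by_group: dict | None = None,
) -> list[TEAnnotation]:
    """Place non-overlapping copies of one family, Poisson per 40-kb bin."""
    n_bins = per_bin_rate.size
    counts = rng.poisson(per_bin_rate)
    records = []
    for b in range(n_bins):
        n = counts[b]
        if n == 0:
            continue
        bin_start = b * cfg.bin_size
        lengths = np.maximum(
            rng.normal(length_mean, length_sd, n), cfg.alu_length_min
        ).astype(np.int64)
        lengths = np.minimum(lengths, cfg.bin_size)
        starts = bin_start + (
            rng.random(n) * (cfg.bin_size - lengths)
        ).astype(np.int64)
        order = np.argsort(starts)
        starts, lengths = starts[order], lengths[order]
        # drop overlapping successors (within-family non-overlap)
        last_end = -1
        names = rng.choice(len(subfamily_names), n, p=subfamily_probs)
        for s, ln, name_idx in zip(starts, lengths, names):
            if s < last_end:
                continue
            sub = subfamily_names[name_idx]
            if divergence_by_group is not None:
                base = divergence_by_group[subfamily_group(sub)]
            else:
                base = 10.0
            div = round(max(0.1, base + rng.normal(0, 1.5)), 1)
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                TEAnnotation(
                    GenomicInterval(chrom, int(s), int(s + ln), strand=strand),
                    te_class,
                    family,
                    sub,
                    divergence=div,
                )
            )
            last_end = s + ln
    return records


def _simulate_repeats(cfg, rng, contacts) -> list[TEAnnotation]:
    records = []
    # Alu subfamily names weighted so group totals follow subfamily_mix
    alu_names, alu_probs = [], []
    for group, mix in zip(("AluJ", "AluS", "AluY"), cfg.subfamily_mix):
        names = _ALU_NAMES[group]
        alu_names.extend(names)
        alu_probs.extend([mix / len(names)] * len(names))
    for chrom, data in contacts.items():
        fbar = data["fbar"]
        alu_rate = cfg.alu_rate_intercept + cfg.alu_rate_slope * fbar
        records.extend(
            _place_family(
                cfg, rng, chrom, alu_rate,
                cfg.alu_length_mean, cfg.alu_length_sd,
                "SINE", "Alu", alu_names, np.array(alu_probs),
                divergence_by_group=_ALU_DIV,
            )
        )
        flat = {
            "L1": (cfg.l1_rate, cfg.l1_length_mean, cfg.l1_length_sd),
            "LTR": (cfg.ltr_rate, cfg.ltr_length_mean, cfg.ltr_length_sd),
            "DNA": (cfg.dna_rate, cfg.dna_length_mean, cfg.dna_length_sd),
            "MIR": (cfg.mir_rate, cfg.mir_length_mean, cfg.mir_length_sd),
        }
        for key, (rate, lmean, lsd) in flat.items():
            te_class, family, names = _OTHER_FAMILIES[key]
            records.extend(
                _place_family(
                    cfg, rng, chrom, np.full(fbar.size, rate),
                    lmean, lsd, te_class, family, names,
                )
            )
    return records


def _simulate_genes(cfg, rng) -> list[GeneLocus]:
    genes = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        n = cfg.genes_per_chrom
        # non-overlapping loci: sorted anchor points with room for lengths
        anchors = np.sort(
            rng.choice(cfg.chrom_length // 100_000, n, replace=False)
        ) * 100_000
        for g, anchor in enumerate(anchors):
            length = int(rng.integers(5_000, 80_000))
            start = int(anchor)
            end = min(start + length, cfg.chrom_length)
            strand = "+" if rng.random() < 0.5 else "-"
            n_tss = int(rng.integers(1, 4))
            if strand == "+":
                tss = np.minimum(start + rng.integers(0, 3_000, n_tss), end)
            else:
                tss = np.maximum(end - rng.integers(0, 3_000, n_tss), start)
            genes.append(
                GeneLocus(
                    GenomicInterval(chrom, start, end, strand=strand),
                    symbol=f"GENE{c + 1}_{g + 1}",
                    strand=strand,
                    tss_positions=tuple(sorted(set(int(t) for t in tss))),
                )
            )
    return genes


def _simulate_peaks(cfg, rng, contacts, repeats, genes) -> dict:
    """Enhancer-mark (me1+ac) and promoter-mark (me3) peaks per chromosome."""
    alu_by_chrom = {}
    for te in repeats:
        if te.family == "Alu":
            alu_by_chrom.setdefault(te.interval.chrom, []).append(te.interval)
    tss_by_chrom = {}
    for gene in genes:
        for t in gene.tss_positions:
            tss_by_chrom.setdefault(gene.interval.chrom, []).append(t)
    peaks = {"h3k4me1": [], "h3k27ac": [], "h3k4me3": []}
    for chrom, data in contacts.items():
        fbar = data["fbar"]
        n_bins = fbar.size
        alus = sorted(alu_by_chrom.get(chrom, []), key=lambda iv: iv.start)
        alu_starts = np.array([iv.start for iv in alus], dtype=np.int64)
        tss_sorted = np.sort(np.array(tss_by_chrom.get(chrom, []), dtype=np.int64))

        enh_counts = rng.poisson(
            cfg.enhancer_rate_intercept + cfg.enhancer_rate_slope * fbar
        )
        me3_counts = rng.poisson(
            cfg.tss_rate_intercept + cfg.tss_rate_slope * fbar
        )
        for b in range(n_bins):
            lo, hi = b * cfg.bin_size, (b + 1) * cfg.bin_size
            for _ in range(enh_counts[b]):
                in_alu = rng.random() < cfg.enhancer_alu_fraction
                center = None
                if in_alu and alu_starts.size:
                    k0 = np.searchsorted(alu_starts, lo, side="left")
                    k1 = np.searchsorted(alu_starts, hi, side="left")
                    if k1 > k0:
                        iv = alus[int(rng.integers(k0, k1))]
                        center = int(rng.integers(iv.start, iv.end))
                if center is None:
                    center = int(rng.integers(lo, hi))
                w1 = int(rng.integers(300, 800))
                w2 = int(rng.integers(200, 600))
                for mark, w in (("h3k4me1", w1), ("h3k27ac", w2)):
                    start = max(0, center - w)
                    end = min(cfg.chrom_length, center + w)
                    peaks[mark].append(
                        Peak(
                            GenomicInterval(chrom, start, end),
                            summit_offset=center - start,
                            signal=float(round(1.0 + rng.exponential(2.0), 3)),
                        )
                    )
            if me3_counts[b] and tss_sorted.size:
                k0 = np.searchsorted(tss_sorted, lo, side="left")
                k1 = np.searchsorted(tss_sorted, hi, side="left")
                if k1 == k0:
                    continue
                for _ in range(me3_counts[b]):
                    t = int(tss_sorted[int(rng.integers(k0, k1))])
                    start = max(0, t - 500)
                    end = min(cfg.chrom_length, t + 500)
                    peaks["h3k4me3"].append(
                        Peak(
                            GenomicInterval(chrom, start, end),
                            summit_offset=t - start,
                            signal=float(round(1.0 + rng.exponential(2.0), 3)),
                        )
                    )
    return peaks


def _plant_cpgs(rng, length: int, rate_arr: np.ndarray) -> np.ndarray:
    """Positions of planted CpG starts, no two adjacent, vectorised draw."""
    u = rng.random(length - 1)
    candidates = np.flatnonzero(u < rate_arr[:-1])
    keep = []
    last = -2
    for pos in candidates:
        if pos > last + 1:
            keep.append(pos)
            last = pos
    return np.asarray(keep, dtype=np.int64)


def _simulate_sequence(cfg, rng, chrom: str, alu_ivs) -> np.ndarray:
    """One chromosome as a uint8 base array with elevated GC/CpG in Alus.

    The non-CpG fill probability is adjusted per region class so the total
    GC fraction matches gc_alu / gc_background after CpG planting.
    """
    length = cfg.chrom_length
    rate = np.full(length, cfg.cpg_rate_background)
    alu_mask = np.zeros(length, dtype=bool)
    for iv in alu_ivs:
        alu_mask[iv.start : iv.end] = True
    rate[alu_mask] = cfg.cpg_rate_alu
    planted = _plant_cpgs(rng, length, rate)

    planted_mask = np.zeros(length, dtype=bool)
    planted_mask[planted] = True
    planted_mask[planted + 1] = True

    seq = np.empty(length, dtype=np.uint8)
    for mask, gc in ((~alu_mask, cfg.gc_background), (alu_mask, cfg.gc_alu)):
        free = mask & ~planted_mask
        n_free = int(free.sum())
        n_planted_bases = int((mask & planted_mask).sum())
        n_total = n_free + n_planted_bases
        if n_total == 0:
            continue
        target_gc = gc * n_total - n_planted_bases
        g_eff = min(max(target_gc / max(n_free, 1), 0.0), 1.0)
        u = rng.random(n_free)
        v = rng.random(n_free)
        bases = np.where(
            u < g_eff,
            np.where(v < 0.5, _C, _G),
            np.where(v < 0.5, ord("A"), ord("T")),
        ).astype(np.uint8)
        seq[free] = bases
    seq[planted] = _C
    seq[planted + 1] = _G
    return seq


def _call_methylome(cfg, rng, chrom, seq, alu_records, genes) -> list[CpGSite]:
    """Binary methylation calls for every CG dinucleotide in the sequence."""
    cg_pos = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
    rate = np.full(cg_pos.size, cfg.meth_rate["other"])
    # gene bodies, then promoters, then Alu subfamilies (highest precedence)
    starts = np.zeros(0, dtype=np.int64)
    if genes:
        g_start = np.array([g.interval.start for g in genes], dtype=np.int64)
        g_end = np.array([g.interval.end for g in genes], dtype=np.int64)
        order = np.argsort(g_start)
        g_start, g_end = g_start[order], g_end[order]
        idx = np.searchsorted(g_start, cg_pos, side="right") - 1
        in_gene = (idx >= 0) & (cg_pos < g_end[np.maximum(idx, 0)])
        rate[in_gene] = cfg.meth_rate["gene_body"]
        tss = np.sort(
            np.array(
                [t for g in genes for t in g.tss_positions], dtype=np.int64
            )
        )
        if tss.size:
            near = np.searchsorted(tss, cg_pos)
            dist = np.full(cg_pos.size, np.iinfo(np.int64).max)
            right_ok = near < tss.size
            dist[right_ok] = np.abs(tss[near[right_ok]] - cg_pos[right_ok])
            left_ok = near > 0
            dist[left_ok] = np.minimum(
                dist[left_ok], np.abs(cg_pos[left_ok] - tss[near[left_ok] - 1])
            )
            rate[dist <= cfg.promoter_halfwidth] = cfg.meth_rate["promoter"]
    if alu_records:
        a_start = np.array([t.interval.start for t in alu_records], dtype=np.int64)
        a_end = np.array([t.interval.end for t in alu_records], dtype=np.int64)
        groups = np.array(
            [subfamily_group(t.subfamily) for t in alu_records]
        )
        order = np.argsort(a_start)
        a_start, a_end, groups = a_start[order], a_end[order], groups[order]
        idx = np.searchsorted(a_start, cg_pos, side="right") - 1
        inside = (idx >= 0) & (cg_pos < a_end[np.maximum(idx, 0)])
        for group in ("AluJ", "AluS", "AluY"):
            sel = inside & (groups[np.maximum(idx, 0)] == group)
            rate[sel] = cfg.meth_rate[group]
    meth = rng.random(cg_pos.size) < rate
    return [
        CpGSite(chrom, int(p), bool(m)) for p, m in zip(cg_pos, meth)
    ]


# ---------------------------------------------------------------------------
# top-level entry points
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig, include_sequence: bool = True) -> Bundle:
    """Generate a complete in-memory bundle (deterministic under the seed).

    ``include_sequence=False`` skips the genome/methylome (for analyses that
    only need contacts and repeat annotation).
    """
    rng = np.random.default_rng(config.seed)
    contacts = _simulate_contacts(config, rng)
    repeats = _simulate_repeats(config, rng, contacts)
    genes = _simulate_genes(config, rng)
    peaks = _simulate_peaks(config, rng, contacts, repeats, genes)

    genome = None
    cpg_sites: list[CpGSite] = []
    realized_meth: dict[str, float] = {}
    if include_sequence:
        genome = {}
        meth_n = {g: 0 for g in ("AluJ", "AluS", "AluY")}
        meth_k = {g: 0 for g in ("AluJ", "AluS", "AluY")}
        for chrom in contacts:
            alu_recs = [
                t for t in repeats
                if t.family == "Alu" and t.interval.chrom == chrom
            ]
            seq = _simulate_sequence(
                config, rng, chrom, [t.interval for t in alu_recs]
            )
            genome[chrom] = seq.tobytes().decode("ascii")
            chrom_genes = [g for g in genes if g.interval.chrom == chrom]
            sites = _call_methylome(config, rng, chrom, seq, alu_recs, chrom_genes)
            cpg_sites.extend(sites)
            # realized per-subfamily rates for the manifest
            a_start = np.array(
                [t.interval.start for t in alu_recs], dtype=np.int64
            )
            a_end = np.array([t.interval.end for t in alu_recs], dtype=np.int64)
            grp = np.array([subfamily_group(t.subfamily) for t in alu_recs])
            order = np.argsort(a_start)
            a_start, a_end, grp = a_start[order], a_end[order], grp[order]
            pos = np.array([s.pos for s in sites], dtype=np.int64)
            meth = np.array([s.methylated for s in sites], dtype=bool)
            idx = np.searchsorted(a_start, pos, side="right") - 1
            inside = (idx >= 0) & (pos < a_end[np.maximum(idx, 0)])
            for group in meth_n:
                sel = inside & (grp[np.maximum(idx, 0)] == group)
                meth_n[group] += int(sel.sum())
                meth_k[group] += int(meth[sel].sum())
        realized_meth = {
            g: (meth_k[g] / meth_n[g] if meth_n[g] else float("nan"))
            for g in meth_n
        }

    # liftover emulation: drop a seeded fraction of bins and the pairs
    # touching them (coordinates that "fail to remap")
    n_bins = config.chrom_length // config.bin_size
    dropped: dict[str, set] = {}
    for chrom in contacts:
        n_drop = int(round(config.liftover_drop_fraction * n_bins))
        drop = rng.choice(n_bins, size=n_drop, replace=False)
        dropped[chrom] = set(int(d) for d in drop)

    binpairs = []
    domains = []
    for chrom, data in contacts.items():
        for s, e in zip(data["dom_starts"], data["dom_ends"]):
            domains.append(Domain(GenomicInterval(chrom, int(s), int(e))))
        bad = dropped[chrom]
        for i, j, f in zip(data["ii"], data["jj"], data["freq"]):
            if int(i) in bad or int(j) in bad:
                continue
            binpairs.append(
                BinPair(
                    chrom,
                    int(i) * config.bin_size,
                    int(j) * config.bin_size,
                    float(f),
                    bin_size=config.bin_size,
                )
            )

    alu_count = sum(1 for t in repeats if t.family == "Alu")
    sign = "+" if config.alu_rate_slope > 0 else (
        "-" if config.alu_rate_slope < 0 else "none"
    )
    coupling = {"Alu": sign, "L1": "none", "LTR": "none", "DNA": "none",
                "MIR": "none"}
    expected_positive = (
        ["Alu:density", "Alu:coverage", "Alu:enrichment_score",
         "SINE:density", "SINE:coverage"]
        if config.alu_rate_slope > 0
        else []
    )
    manifest = TruthManifest(
        config=config,
        coupling_sign=coupling,
        alu_copy_count=alu_count,
        realized_meth_rate=realized_meth,
        expected_positive_metrics=expected_positive,
    )
    chrom_sizes = {f"chr{c + 1}": config.chrom_length
                   for c in range(config.n_chrom)}
    return Bundle(
        config=config,
        chrom_sizes=chrom_sizes,
        domains=domains,
        binpairs=binpairs,
        repeats=repeats,
        genes=genes,
        peaks=peaks,
        genome=genome,
        cpg_sites=cpg_sites,
        manifest=manifest,
    )


BUNDLE_FILES = (
    "genome.fasta", "domains.bed", "binpairs.tsv", "repeats.out", "cpg.tsv",
    "peaks_h3k4me1.narrowPeak", "peaks_h3k27ac.narrowPeak",
    "peaks_h3k4me3.narrowPeak", "genes.tsv", "truth.json",
)


def simulate_all(config: SimConfig, out_dir) -> TruthManifest:
    """Generate the bundle and write every file to ``out_dir``.

    Identical config (including seed) produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config, include_sequence=True)
    write_fasta(bundle.genome, out / "genome.fasta")
    write_records(bundle.domains, out / "domains.bed", "domain_bed")
    write_records(bundle.binpairs, out / "binpairs.tsv", "binpair_tsv")
    write_records(bundle.repeats, out / "repeats.out", "rmsk_out")
    write_records(bundle.cpg_sites, out / "cpg.tsv", "cpg_tsv")
    for mark in ("h3k4me1", "h3k27ac", "h3k4me3"):
        write_records(
            bundle.peaks[mark], out / f"peaks_{mark}.narrowPeak", "narrowPeak"
        )
    write_records(bundle.genes, out / "genes.tsv", "genes_tsv")
    (out / "truth.json").write_text(bundle.manifest.to_json() + "\n")
    return bundle.manifest


def planted_binned_correlation(
    manifest: TruthManifest,
    n_reps: int = 200,
    n_bins: int = 50,
    seed: int = 12345,
) -> dict:
    """Expected sign and Monte-Carlo 95% band of the binned density
    correlation per family, under the bundle's own generative model.

    Each replicate re-simulates the contact skeleton and per-bin Poisson
    copy counts (no sequence), then computes the binned Pearson r the
    pipeline would measure for retained intra-domain pairs.
    """
    from .enrichment import bin_by_frequency, correlate_bins

    cfg = manifest.config
    rng = np.random.default_rng(seed)
    fam_rates = {
        "Alu": None,  # coupled
        "L1": cfg.l1_rate,
        "LTR": cfg.ltr_rate,
        "DNA": cfg.dna_rate,
        "MIR": cfg.mir_rate,
    }
    results = {fam: [] for fam in fam_rates}
    for _ in range(n_reps):
        contacts = _simulate_contacts(cfg, rng)
        freqs, dens = {f: [] for f in fam_rates}, {f: [] for f in fam_rates}
        for data in contacts.values():
            intra = data["intra"]
            f = data["freq"][intra]
            keep = f >= cfg.inter_freq_mean  # proxy for the lower threshold
            ii, jj = data["ii"][intra][keep], data["jj"][intra][keep]
            f = f[keep]
            n_bins_chrom = data["fbar"].size
            for fam, rate in fam_rates.items():
                if rate is None:
                    lam = cfg.alu_rate_intercept + cfg.alu_rate_slope * data["fbar"]
                else:
                    lam = np.full(n_bins_chrom, rate)
                counts = rng.poisson(lam)
                dens[fam].append(counts[ii] + counts[jj])
                freqs[fam].append(f)
        for fam in fam_rates:
            x = np.concatenate(freqs[fam])
            y = np.concatenate(dens[fam]).astype(float)
            bins = bin_by_frequency(x, y, n_bins)
            results[fam].append(correlate_bins(bins).r)
    out = {}
    for fam in fam_rates:
        rs = np.array(results[fam])
        if fam == "Alu":
            sign = "+" if cfg.alu_rate_slope > 0 else (
                "-" if cfg.alu_rate_slope < 0 else "0")
        else:
            sign = "0"
        out[fam] = {
            "sign": sign,
            "band": (float(np.quantile(rs, 0.025)),
                     float(np.quantile(rs, 0.975))),
            "median_r": float(np.median(rs)),
        }
    return out
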