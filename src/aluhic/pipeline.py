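"""End-to-end orchestration: simulate/load, filter, correlate, report.

``run_all`` executes the stages in order (simulate? -> filter -> TE
enrichment -> sequence composition -> regulatory elements) and assembles a
JSON-serializable run report. Regenerating from the same inputs and seeds
reproduces the report bit for bit except the timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cifilter import stratify_and_filter, filter_binpairs
from .composition import (
    GenomeComposition,
    composition_vs_frequency,
    subfamily_methylation,
)
from .enrichment import (
    CorrelationResult,
    TEIndex,
    bin_by_frequency,
    correlate_bins,
    family_profile,
)
from .io import read_fasta, read_records, write_records
from .regulatory import (
    background_coverage,
    call_active_enhancers,
    call_active_tss,
    classify_enhancer_origin,
    count_in_binpair,
    coverage_enrichment_test,
    deredundant_loci,
    element_coverage_correlation,
    flank_coverage,
    group_bins_by_coverage,
    match_peak_sets,
)
from .simulate import default_config, simulate_all
from .types import GenomicInterval

logger = logging.getLogger(__name__)

INPUT_FILES = {
    "genome": "genome.fasta",
    "domains": "domains.bed",
    "binpairs": "binpairs.tsv",
    "repeats": "repeats.out",
    "cpg": "cpg.tsv",
    "me1": "peaks_h3k4me1.narrowPeak",
    "ac": "peaks_h3k27ac.narrowPeak",
    "me3": "peaks_h3k4me3.narrowPeak",
    "genes": "genes.tsv",
}

_DIALECT = {
    "domains": "domain_bed",
    "binpairs": "binpair_tsv",
    "repeats": "rmsk_out",
    "cpg": "cpg_tsv",
    "me1": "narrowPeak",
    "ac": "narrowPeak",
    "me3": "narrowPeak",
    "genes": "genes_tsv",
}

ALLOWED_BINS = (20, 50, 100)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (CLI flags have config twins)."""

    input_dir: str | None = None  # directory containing the standard bundle
    out_dir: str = "aluhic_out"
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)
    n_bins: int = 50
    allow_any_bins: bool = False
    metric_kind: str = "density"
    strata: tuple = ("intra", "non_intra")
    flank: int = 20_000
    groups: int = 5
    n_background: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_bins not in ALLOWED_BINS and not self.allow_any_bins:
            raise ValueError(
                f"n_bins must be one of {ALLOWED_BINS} "
                "(set allow_any_bins to override)"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown RunConfig fields: {sorted(unknown)}")
        if "strata" in payload:
            payload["strata"] = tuple(payload["strata"])
        return cls(**payload)


def _corr_dict(res: CorrelationResult | None):
    if res is None:
        return None
    return {"r": res.r, "p": res.p, "n": res.n, "label": res.label}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_bundle(paths: dict) -> list[str]:
    """Cross-file consistency checks; returns violation messages.

    Checks: every CpG call is a CG dinucleotide inside its chromosome;
    every repeat and domain lies within chromosome bounds; bin-pair bins
    fall inside their chromosome; domain boundaries align to the bin grid
    implied by the bin-pair list.
    """
    violations: list[str] = []
    genome = read_fasta(paths["genome"])
    sizes = {c: len(s) for c, s in genome.items()}

    repeats = read_records(paths["repeats"], "rmsk_out")
    for t in repeats:
        iv = t.interval
        if iv.chrom not in sizes:
            violations.append(f"repeat on unknown chromosome {iv.chrom}")
        elif iv.end > sizes[iv.chrom]:
            violations.append(
                f"repeat {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
            )
    domains = read_records(paths["domains"], "domain_bed")
    pairs = read_records(paths["binpairs"], "binpair_tsv")
    bin_size = pairs[0].bin_size if pairs else 40_000
    for d in domains:
        iv = d.interval
        if iv.chrom not in sizes:
            violations.append(f"domain on unknown chromosome {iv.chrom}")
        elif iv.end > sizes[iv.chrom]:
            violations.append(
                f"domain {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
            )
        if iv.start % bin_size or iv.end % bin_size:
            violations.append(
                f"domain {iv.chrom}:{iv.start}-{iv.end} off the bin grid"
            )
    for p in pairs:
        if p.chrom not in sizes:
            violations.append(f"bin-pair on unknown chromosome {p.chrom}")
        elif p.start_j + p.bin_size > sizes[p.chrom]:
            violations.append(
                f"bin-pair {p.chrom}:{p.start_i}/{p.start_j} beyond chromosome end"
            )
    cpg = read_records(paths["cpg"], "cpg_tsv")
    for s in cpg:
        if s.chrom not in sizes:
            violations.append(f"CpG call on unknown chromosome {s.chrom}")
            continue
        seq = genome[s.chrom]
        if seq[s.pos : s.pos + 2].upper() != "CG":
            violations.append(
                f"CpG call at {s.chrom}:{s.pos} is not a CG dinucleotide"
            )
    return violations


def _resolve_paths(config: RunConfig) -> dict:
    base = Path(config.input_dir)
    paths = {key: base / fname for key, fname in INPUT_FILES.items()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    return paths


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        logger.info("stage=simulate out=%s", out / "inputs")
        sim_cfg = default_config({**config.sim_overrides, "seed": config.seed})
        simulate_all(sim_cfg, out / "inputs")
        config.input_dir = str(out / "inputs")
    if not config.input_dir:
        raise ValueError("input_dir is required unless simulate=true")
    paths = _resolve_paths(config)

    report: dict = {
        "software": {"name": "aluhic", "version": __version__},
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
        },
        "input_checksums": {k: _checksum(p) for k, p in sorted(paths.items())},
    }

    # ------------------------------------------------------------- load
    logger.info("stage=load inputs=%s", config.input_dir)
    genome = read_fasta(paths["genome"])
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    domains = read_records(paths["domains"], "domain_bed")
    pairs = read_records(paths["binpairs"], "binpair_tsv")
    repeats = read_records(paths["repeats"], "rmsk_out")
    cpg = read_records(paths["cpg"], "cpg_tsv")
    me1 = read_records(paths["me1"], "narrowPeak")
    ac = read_records(paths["ac"], "narrowPeak")
    me3 = read_records(paths["me3"], "narrowPeak")
    genes = read_records(paths["genes"], "genes_tsv")
    index = TEIndex(repeats)

    # ----------------------------------------------------------- filter
    logger.info("stage=filter pairs=%d domains=%d", len(pairs), len(domains))
    strat = stratify_and_filter(pairs, domains)
    report["thresholds"] = {
        "lower": strat.lower_threshold,
        "upper": strat.upper_threshold,
        "retained_intra": len(strat.intra),
        "non_intra": len(strat.non_intra),
        "boundary": len(strat.boundary),
        "removed_low": strat.removed_low_count,
        "removed_high": strat.removed_high_count,
        "removed_high_fraction": strat.removed_high_fraction,
        "self_pairs_excluded": True,
    }
    write_records(strat.intra, out / "retained_intra.tsv", "binpair_tsv")

    # ------------------------------------------------------------ enrich
    logger.info("stage=enrich retained=%d", len(strat.intra))
    report["te_correlations"] = {}
    strata_pairs = {}
    if "intra" in config.strata:
        strata_pairs["intra"] = strat.intra
    if "non_intra" in config.strata and len(strat.non_intra) >= 3:
        # non-intra reuses the thresholds derived from this run
        filtered = filter_binpairs(
            strat.non_intra, strat.lower_threshold, strat.upper_threshold
        )
        if len(filtered.retained) >= 3:
            strata_pairs["non_intra"] = filtered.retained
    for stratum, spairs in strata_pairs.items():
        try:
            profile = family_profile(
                spairs, index, n_bins=config.n_bins, kind=config.metric_kind
            )
        except ValueError as exc:
            logger.warning("stratum %s: %s", stratum, exc)
            continue
        report["te_correlations"][stratum] = {
            sel: _corr_dict(res) for sel, res in profile.items()
        }

    # ------------------------------------------------------- composition
    logger.info("stage=composition")
    comp = GenomeComposition(genome, index, cpg)
    comp_corr = composition_vs_frequency(
        strat.intra, genome, index, cpg, n_bins=config.n_bins, comp=comp
    )
    report["composition_correlations"] = {
        f"{q}:{c}": _corr_dict(res) for (q, c), res in comp_corr.items()
    }
    report["subfamily_methylation"] = subfamily_methylation(cpg, index)

    # -------------------------------------------------------- regulatory
    logger.info("stage=regulatory")
    enhancers = call_active_enhancers(me1, ac)
    tss = call_active_tss(deredundant_loci(genes), me3)
    freqs = np.array([p.frequency for p in strat.intra])
    reg_corr = {}
    for name, elements in (("enhancers", enhancers), ("active_tss", tss)):
        counts = np.array(
            [count_in_binpair(elements, p) for p in strat.intra], dtype=float
        )
        try:
            bins = bin_by_frequency(freqs, counts, config.n_bins)
            reg_corr[name] = _corr_dict(correlate_bins(bins, label=name))
        except ValueError as exc:
            logger.warning("%s count correlation: %s", name, exc)
            reg_corr[name] = None
    report["element_frequency_correlations"] = reg_corr

    bin_size = strat.intra[0].bin_size if strat.intra else 40_000
    all_bins = [
        GenomicInterval(chrom, s, s + bin_size)
        for chrom, size in chrom_sizes.items()
        for s in range(0, size - bin_size + 1, bin_size)
    ]
    groups = group_bins_by_coverage(all_bins, index, k=config.groups)
    report["alu_coverage_group_correlations"] = {
        name: _corr_dict(element_coverage_correlation(groups, elements))
        for name, elements in (("enhancers", enhancers), ("active_tss", tss))
    }

    origins = classify_enhancer_origin(enhancers, index)
    bg_cov, bg_mean = background_coverage(
        chrom_sizes, index, config.n_background,
        width=2 * config.flank, seed=config.seed,
    )
    tests = {}
    for origin in ("Alu_derived", "non_Alu"):
        subset = [e for e, o in zip(enhancers, origins) if o == origin]
        if not subset:
            tests[origin] = None
            continue
        obs = flank_coverage(subset, index, flank=config.flank,
                             chrom_sizes=chrom_sizes)
        entry = {}
        for method in ("binomial", "permutation"):
            res = coverage_enrichment_test(
                obs, bg_cov, method=method, seed=config.seed
            )
            entry[method] = dataclasses.asdict(res)
        entry["mean_flank_coverage"] = float(obs.mean())
        tests[origin] = entry
    report["enhancer_alu_enrichment"] = {
        "background_mean_coverage": bg_mean,
        "tests": tests,
    }
    report["peak_sharing_me1_vs_ac"] = dataclasses.asdict(
        match_peak_sets(me1, ac)
    )
    report["counts"] = {
        "enhancers": len(enhancers),
        "active_tss": len(tss),
        "alu_derived_enhancers": origins.count("Alu_derived"),
        "repeats": len(repeats),
        "cpg_sites": len(cpg),
    }
    report["elapsed_seconds"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    logger.info("stage=report out=%s", out / "report.json")
    return report
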